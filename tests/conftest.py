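from pathlib import Path

import pytest

from magqc.fixtures import demo_spec, make_fixture


@pytest.fixture(scope="session")
def demo_dataset(tmp_path_factory) -> Path:
    """A five-bin synthetic dataset covering every quality category."""
    out = tmp_path_factory.mktemp("demo_dataset")
    make_fixture(demo_spec(seed=42), out)
    return out


def write_fasta(path: Path, records: dict[str, str]) -> Path:
    lines = []
    for name, seq in records.items():
        lines.append(f">{name}")
        lines.append(seq)
    path.write_text("\n".join(lines) + "\n")
    return path
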