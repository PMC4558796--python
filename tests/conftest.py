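import pytest

from blockshift import Config, make_case


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free case with no planted error (starting == true)."""
    return make_case(seed=11, signal_strength=1.0, planted_shifts=[0, 0, 0])


@pytest.fixture(scope="session")
def shifted_case():
    """Noise-free case with one block misaligned by +2."""
    return make_case(seed=11, signal_strength=1.0, planted_shifts=[0, 2, 0])


@pytest.fixture()
def og_config():
    return Config(mode="O+G")


def write_afa(tmp_path, name, records):
    """Write (id, row) pairs as an aligned FASTA file; return the path."""
    p = tmp_path / name
    p.write_text("".join(f">{rid}\n{row}\n" for rid, row in records))
    return p
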