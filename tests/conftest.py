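import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(content: str, name: str = "test.fasta"):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write


@pytest.fixture
def gff3_file(tmp_path):
    def _write(content: str, name: str = "test.gff3"):
        p = tmp_path / name
        if not content.startswith("##gff-version"):
            content = "##gff-version 3\n" + content
        p.write_text(content)
        return p

    return _write
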