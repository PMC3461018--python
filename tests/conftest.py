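import numpy as np
import pytest

from waveseq import GenomeDef, Read


@pytest.fixture
def small_genome():
    return GenomeDef.from_dict({"chrA": 100_000, "chrB": 60_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_reads(spec):
    """Turn (chrom, start, end, strand) tuples into Read objects."""
    return [Read(*row) for row in spec]


@pytest.fixture
def bed_file(tmp_path):
    """Write BED lines to a temp file and return its path."""

    def _write(lines, name="reads.bed"):
        path = tmp_path / name
        path.write_text("".join(line + "\n" for line in lines))
        return path

    return _write
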