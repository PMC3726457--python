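import numpy as np
import pytest

from novtx import GenomicInterval, TranscriptModel, paper_preset, simulate_cohort

# Published validation-assay primers (transcript, role, sequence, length, Tm degC).
# The UU18303 R row repeats the F sequence with a 0.01 degC different printed Tm;
# rows are carried verbatim.
TABLE1_PRIMERS = [
    ("UU18303", "F", "GAAGGAGAGCAGAGCTTGGA", 20, 59.83),
    ("UU18303", "R", "GAAGGAGAGCAGAGCTTGGA", 20, 59.84),
    ("UU12205", "F1", "AGGAGTGTGCATCCCACTTT", 20, 59.58),
    ("UU12205", "F2", "TGAGAAGGAAGCCAAGGAAA", 20, 59.93),
    ("UU12205", "R1", "TAATGCCTGGCCTATGGAAG", 20, 60.05),
    ("UU12205", "R2", "TTGTTACTGTGCGAACTCTGC", 21, 59.14),
    ("UU18376", "F1", "TGTGAAGGAGGTGAACTGGA", 20, 59.23),
    ("UU18376", "F2", "AACTGCCCAAGTCACACAGTT", 21, 59.68),
    ("UU18376", "R1", "GAATTTGCTTCTGTGCGTTG", 20, 59.47),
    ("UU18376", "R2", "AACTGTGTGACTTGGGCAGTT", 21, 59.68),
    ("UU18376", "R3", "ACTTGCCCTCTCTCGGTCTT", 20, 60.39),
    ("UU1814", "F", "TTTGTACAGGGCCCTTTGTG", 20, 60.91),
    ("UU1814", "R", "GCAGTCTCTTCACCCAGCTC", 20, 60.14),
    ("RPLP0", "F", "CTTCATTGTGGGAGCAGACA", 20, 59.83),
    ("RPLP0", "R", "GCCTTGACCTTTTCAGCAAG", 20, 59.99),
]


@pytest.fixture
def rng():
    return np.random.default_rng(20130729)


@pytest.fixture(scope="session")
def paper_cohort():
    """One full paper-preset cohort, shared across tests (seed fixed)."""
    return simulate_cohort(paper_preset(seed=0))


def make_model(tid, exon_coords, chrom="chr1", strand="+", depth=0.0):
    return TranscriptModel(
        tid,
        [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords],
        depth=depth,
    )


@pytest.fixture
def random_model_factory(rng):
    def factory(tid="T", chrom="chr1", max_exons=6):
        n = int(rng.integers(1, max_exons + 1))
        pos = int(rng.integers(1, 10_000))
        exons = []
        for _ in range(n):
            length = int(rng.integers(30, 400))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(50, 800))
        return make_model(tid, exons, chrom=chrom,
                          strand="+" if rng.random() < 0.5 else "-",
                          depth=float(rng.integers(0, 200)))

    return factory
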