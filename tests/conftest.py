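import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from ptseq.qc import TAG_SEQUENCE, ILLUMINA_ADAPTER, SequencedRead


def q(n, phred=37):
    return chr(phred + 33) * n


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_qc_fixture():
    """Seven reads for ICDS-mode QC: one removed by each cleanup rule
    (adapter-emptied, 5'-N-emptied, quality-emptied, >10% N, <25 bp),
    one tag-negative read, and one clean tagged survivor.

    Returns (reads, expected_survivor_ids, expected_removal_counts).
    """
    tag = TAG_SEQUENCE
    clean30 = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 bp, unique-ish
    reads = [
        # entirely adapter: clipped to empty
        SequencedRead("r_adapter", ILLUMINA_ADAPTER, q(len(ILLUMINA_ADAPTER))),
        # all-N: 5' non-ACGT trim empties it
        SequencedRead("r_fiveprime", "N" * 30, q(30)),
        # tagged but every base below Q20: 3' quality trim empties it
        SequencedRead("r_quality", tag + clean30, q(len(tag) + 30, phred=5)),
        # tagged, 5/30 = 16.7% N after tag removal
        SequencedRead("r_nfrac", tag + "ACGTANCGTANCGTANCGTANCGTANCGTA",
                      q(len(tag) + 30)),
        # tagged but only 20 bp of insert: < 25 bp
        SequencedRead("r_short", tag + clean30[:20], q(len(tag) + 20)),
        # clean but no tag: removed in ICDS mode
        SequencedRead("r_untagged", clean30, q(30)),
        # clean tagged survivor
        SequencedRead("r_clean", tag + clean30, q(len(tag) + 30)),
    ]
    expected_removed = {"adapter": 1, "five_prime_n": 1, "quality": 1,
                        "untagged": 1, "n_fraction": 1, "length": 1}
    return reads, ["r_clean"], expected_removed
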