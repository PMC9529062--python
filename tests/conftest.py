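import pytest
from hypothesis import HealthCheck, settings

import dupliseq as dq

settings.register_profile(
    "ci", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# P28-like longitudinal design: six sampling days, founder A, major clone B,
# transient subclone C lost during treatment, minor clone D sweeping at relapse.
TIMEPOINTS = [0, 29, 49, 93, 173, 208]
P28_SPEC = [
    ("A", None, {0: 0.95, 29: 0.05, 49: 0.15, 93: 0.70, 173: 0.80, 208: 0.95}),
    ("B", "A", {0: 0.80, 29: 0.005, 49: 0.06, 93: 0.50, 173: 0.60, 208: 0.88}),
    ("C", "B", {0: 0.45, 29: 0.002, 49: 0.002, 93: 0.0005, 173: 0.0, 208: 0.0}),
    ("D", "B", {0: 0.002, 29: 0.0008, 49: 0.001, 93: 0.002, 173: 0.02, 208: 0.85}),
]


@pytest.fixture(scope="session")
def small_panel():
    return dq.generate_panel(4, 40, seed=11)


@pytest.fixture()
def p28_tree():
    return dq.generate_clone_tree(P28_SPEC, TIMEPOINTS)


@pytest.fixture(scope="session")
def study_scale_panel():
    return dq.generate_panel(71, 89, seed=1)


def make_reads(seqs, *, contig="KRAS_p01", start=0, tag_a="ACGTACGTACGT",
               tag_b="TGCATGCATGCA", orientation="ab", prefix="r",
               softclips=None):
    """Construct a strand family of reads from sequence strings."""
    reads = []
    for i, s in enumerate(seqs):
        reads.append(dq.TaggedRead(
            name=f"{prefix}{i:03d}", contig=contig, start=start,
            end=start + len(s), seq=dq.encode_seq(s), tag_a=tag_a, tag_b=tag_b,
            orientation=orientation,
            softclip=bool(softclips[i]) if softclips is not None else False))
    return reads


def brute_force_sscs(seqs, cutoff):
    """Independent per-position tally oracle for SSCS building.

    Counts bases by hand per column and applies the agreement rule; written
    without numpy so it shares nothing with the implementation path.
    """
    length = len(seqs[0])
    out = []
    for pos in range(length):
        tallies = {}
        denom = 0
        for s in seqs:
            b = s[pos]
            if b == "N":
                continue
            tallies[b] = tallies.get(b, 0) + 1
            denom += 1
        if denom == 0:
            out.append("N")
            continue
        best_base = max(sorted(tallies), key=lambda b: tallies[b])
        out.append(best_base if tallies[best_base] / denom >= cutoff else "N")
    return "".join(out)
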