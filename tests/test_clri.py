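"""Interaction parsing, signed distances, distribution summaries, KS test."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from regulatome.clri import (
    ClriError,
    GenomicInterval,
    InteractionRecord,
    Promoter,
    build_distance_set,
    clri_pipeline,
    ks_two_sample,
    promoter_anchor,
    read_interaction_table,
    read_promoter_table,
    signed_distance,
    summarize_distances,
)
from regulatome.synthetic import SyntheticInteractionSpec, gen_interactions


def _record(chrom_a="chr1", a=(1000, 2000), chrom_b="chr1", b=(500000, 501000), genes_a=(), genes_b=()):
    return InteractionRecord(
        anchor_a=GenomicInterval(chrom_a, *a),
        anchor_b=GenomicInterval(chrom_b, *b),
        genes_a=genes_a,
        genes_b=genes_b,
    )


# ---------------------------------------------------------------- parsing

def test_read_interaction_table(tmp_path):
    path = tmp_path / "ia.tsv"
    path.write_text(
        "chr1\t1001\t2000\tchr1\t500001\t501000\tGENEA\tGENEB\tHiC\tIMR90\n"
        "chr1\t1001\t2000\tchr2\t1\t1000\t\t\n"
        "chr3\t11\t20\tchr3\t31\t40\n"
    )
    records = read_interaction_table(path)
    assert len(records) == 3
    assert records[0].is_cis and records[0].anchor_a.start == 1000  # 1-based converted
    assert records[0].genes_a == ("GENEA",)
    assert not records[1].is_cis
    assert records[2].genes_a == () and records[2].genes_b == ()


def test_read_interaction_table_rejects_bad_rows(tmp_path):
    bad_coord = tmp_path / "bad1.tsv"
    bad_coord.write_text("chr1\tx\t2000\tchr1\t1\t1000\n")
    with pytest.raises(ClriError, match="bad1.tsv:1"):
        read_interaction_table(bad_coord)
    inverted = tmp_path / "bad2.tsv"
    inverted.write_text("chr1\t2001\t2000\tchr1\t1\t1000\n")
    with pytest.raises(ClriError, match="bad2.tsv:1"):
        read_interaction_table(inverted)


def test_read_promoter_table_bed6_and_two_column(tmp_path):
    bed = tmp_path / "p.bed"
    bed.write_text("chr1\t1000000\t1000001\tGENEA\t0\t+\nchr2\t500\t501\tGENEB\t0\t-\n")
    proms = read_promoter_table(bed)
    assert proms["GENEA"] == Promoter("chr1", 1000000, "+")
    two_col = tmp_path / "p2.tsv"
    two_col.write_text("GENEC\t42\n")
    assert read_promoter_table(two_col, chrom="chrX")["GENEC"].tss == 42
    with pytest.raises(ClriError):
        read_promoter_table(two_col)  # chrom required for 2-column form


# ---------------------------------------------------------- signed distance

def test_promoter_anchor_prefers_annotated_gene():
    proms = {"GENEA": Promoter("chr1", 1_000_000), "GENEB": Promoter("chr1", 2_000_000)}
    iv = GenomicInterval("chr1", 100, 200)
    assert promoter_anchor(iv, ("GENEA", "GENEB"), proms) == 1_000_000  # first listed
    assert promoter_anchor(iv, (), proms) == 150  # midpoint fallback
    assert promoter_anchor(iv, ("UNKNOWN",), proms) == 150


def test_signed_distance_convention_and_antisymmetry():
    rec = _record(a=(1_000_000, 1_000_100), b=(1_500_000, 1_500_100), genes_a=("TARGET",))
    d = signed_distance("TARGET", rec, {"TARGET": Promoter("chr1", 1_000_050)})
    assert d == 500_000  # partner midpoint downstream of the promoter
    # exchanging target and partner anchors flips the sign, same magnitude
    flipped = InteractionRecord(
        anchor_a=rec.anchor_b, anchor_b=rec.anchor_a, genes_a=("TARGET",), genes_b=()
    )
    d2 = signed_distance("TARGET", flipped, {"TARGET": Promoter("chr1", 1_500_050)})
    assert d2 == -d
    rec_up = _record(a=(1_500_000, 1_500_100), b=(900_000, 900_100), genes_a=("TARGET",))
    assert signed_distance("TARGET", rec_up, {"TARGET": Promoter("chr1", 1_500_000)}) < 0


def test_signed_distance_excludes_trans_and_both_sides():
    proms = {"TARGET": Promoter("chr1", 1_000_000)}
    trans = _record(chrom_b="chr2", genes_a=("TARGET",))
    with pytest.raises(ClriError):
        signed_distance("TARGET", trans, proms)
    both = _record(genes_a=("TARGET",), genes_b=("TARGET",))
    with pytest.raises(ClriError):
        signed_distance("TARGET", both, proms)


def test_build_distance_set_counts():
    proms = {"G1": Promoter("chr1", 1_000_000)}
    records = [
        _record(a=(1_000_000, 1_000_100), b=(1_200_000, 1_200_100), genes_a=("G1",)),
        _record(a=(1_000_000, 1_000_100), b=(800_000, 800_100), genes_a=("G1",)),
        _record(a=(1_000_000, 1_000_100), chrom_b="chr9", genes_a=("G1",)),
        _record(a=(1_000_000, 1_000_100), b=(700_000, 700_100), genes_a=("G1",), genes_b=("G1",)),
    ]
    dset = build_distance_set(["G1", "ABSENT"], records, proms)
    assert len(dset) == 2
    assert dset.n_trans_excluded == 1
    assert dset.n_both_sides_excluded == 1
    assert dset.per_gene["G1"] == 2
    # a gene in the set but in no record contributes nothing and is not an error
    assert "ABSENT" not in dset.per_gene


def test_build_distance_set_dedupe():
    proms = {"G1": Promoter("chr1", 1_000_000)}
    rec = _record(a=(1_000_000, 1_000_100), b=(1_200_000, 1_200_100), genes_a=("G1",))
    dup = [rec, rec]
    assert len(build_distance_set(["G1"], dup, proms)) == 2
    assert len(build_distance_set(["G1"], dup, proms, dedupe=True)) == 1


# ----------------------------------------------------------------- summary

def test_summarize_distances_binning():
    from regulatome.clri import SignedDistanceSet

    sds = SignedDistanceSet(label="x", distances=[-2_000_000, -500_000, 300_000])
    summary = summarize_distances(sds)
    assert summary.fraction_upstream == pytest.approx(2 / 3)
    assert summary.fraction_downstream == pytest.approx(1 / 3)
    # the two upstream values fall in the [-1e7, -1e5) decades
    upstream_decades = summary.histogram["[-1e7,-1e6)"] + summary.histogram["[-1e6,-1e5)"]
    assert upstream_decades == 2
    assert summary.histogram["[1e5,1e6)"] == 1
    assert sum(summary.histogram.values()) == 3


def test_summarize_mirror_symmetry():
    from regulatome.clri import SignedDistanceSet

    rng = np.random.default_rng(0)
    d = list((rng.uniform(1e4, 1e7, size=50) * rng.choice([-1, 1], size=50)).astype(int))
    fwd = summarize_distances(SignedDistanceSet(label="f", distances=d))
    mirror = summarize_distances(SignedDistanceSet(label="m", distances=[-v for v in d]))
    assert fwd.fraction_upstream == pytest.approx(mirror.fraction_downstream)
    assert fwd.histogram["[1e5,1e6)"] == mirror.histogram["[-1e6,-1e5)"]


def test_summarize_empty_set():
    from regulatome.clri import SignedDistanceSet

    summary = summarize_distances(SignedDistanceSet(label="empty"))
    assert summary.n == 0
    assert summary.fraction_upstream == summary.fraction_downstream == 0.0
    assert all(v == 0 for v in summary.histogram.values())


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.integers(min_value=-10**8, max_value=10**8), min_size=1, max_size=60), st.randoms())
def test_histogram_conserved_under_permutation(distances, rnd):
    from regulatome.clri import SignedDistanceSet

    shuffled = list(distances)
    rnd.shuffle(shuffled)
    a = summarize_distances(SignedDistanceSet(label="a", distances=distances))
    b = summarize_distances(SignedDistanceSet(label="b", distances=shuffled))
    assert a.histogram == b.histogram
    assert sum(a.histogram.values()) == len(distances)


# ---------------------------------------------------------------------- KS

def _brute_force_D(x, y):
    """Independent oracle: max ECDF gap over every pooled threshold."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        gap = abs(np.mean(x <= t) - np.mean(y <= t))
        best = max(best, gap)
    return best


def test_ks_identical_samples():
    r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.D == 0.0 and r.p_asymptotic == 1.0 and r.p_exact == 1.0


def test_ks_disjoint_supports():
    r = ks_two_sample([1, 2, 3], [4, 5, 6])
    assert r.D == 1.0


def test_ks_half_overlap_example():
    # brute force over pooled thresholds of {1,2} vs {1.5,2.5} gives 0.5
    assert _brute_force_D([1, 2], [1.5, 2.5]) == 0.5
    r = ks_two_sample([1, 2], [1.5, 2.5])
    assert r.D == 0.5


def test_ks_rejects_empty_sample():
    with pytest.raises(ClriError):
        ks_two_sample([], [1.0])


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=1, max_size=50),
    st.lists(st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=1, max_size=50),
)
def test_ks_statistic_matches_brute_force(x, y):
    assert ks_two_sample(x, y).D == pytest.approx(_brute_force_D(x, y), abs=1e-12)


@pytest.mark.parametrize("seed", range(12))
def test_ks_exact_close_to_asymptotic_at_seven(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=7), rng.normal(size=7)
    r = ks_two_sample(x, y)
    assert r.p_exact is not None
    assert abs(r.p_exact - r.p_asymptotic) < 0.05


@pytest.mark.parametrize("seed", range(5))
def test_ks_exact_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=6), rng.normal(size=7)
    r = ks_two_sample(x, y)
    ref = ks_2samp(x, y, method="exact")
    assert r.D == pytest.approx(ref.statistic)
    assert r.p_exact == pytest.approx(ref.pvalue)


def test_ks_p_monotone_in_D():
    # same sample sizes, increasing separation => non-increasing p
    base = list(np.linspace(0, 1, 20))
    ps = []
    for shift in (0.0, 0.3, 0.8, 2.0):
        r = ks_two_sample(base, [v + shift for v in base])
        ps.append(r.p_asymptotic)
    assert ps == sorted(ps, reverse=True)


# ----------------------------------------------------------------- pipeline

def _synthetic_pipeline_inputs(beta_up, beta_down, n_genes=10, per_gene=30, seed=0):
    genes_up = tuple(f"UP{i}" for i in range(n_genes))
    genes_down = tuple(f"DN{i}" for i in range(n_genes))
    rec_up, prom_up = gen_interactions(
        SyntheticInteractionSpec(genes=genes_up, interactions_per_gene=per_gene, downstream_prob=beta_up, seed=seed)
    )
    rec_down, prom_down = gen_interactions(
        SyntheticInteractionSpec(genes=genes_down, interactions_per_gene=per_gene, downstream_prob=beta_down, seed=seed + 1)
    )
    return genes_up, genes_down, rec_up + rec_down, {**prom_up, **prom_down}


def test_pipeline_identical_sets_null():
    genes_up, _, records, proms = _synthetic_pipeline_inputs(0.5, 0.5)
    up, down, s_up, s_down, ks = clri_pipeline(genes_up, genes_up, records, proms)
    assert ks.D == 0.0 and ks.p_asymptotic == 1.0


def test_pipeline_biased_sets_reject():
    genes_up, genes_down, records, proms = _synthetic_pipeline_inputs(1.0, 0.5, per_gene=50)
    up, down, s_up, s_down, ks = clri_pipeline(genes_up, genes_down, records, proms)
    assert s_up.fraction_downstream == 1.0  # beta = 1 places everything downstream
    assert ks.D >= 0.4
    assert ks.p_asymptotic < 0.001


def test_pipeline_unmapped_set_raises():
    genes_up, genes_down, records, proms = _synthetic_pipeline_inputs(0.5, 0.5)
    with pytest.raises(ClriError, match="no cis distances"):
        clri_pipeline(["NOWHERE"], genes_down, records, proms)
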