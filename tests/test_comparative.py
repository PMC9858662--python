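"""Domain aggregation, pervasiveness/groups/Venn, tests, and scaling."""

import itertools
import math

import numpy as np
import pytest
from scipy import special

from trnaome import comparative
from trnaome.comparative import (
    classify_groups,
    compare_groups,
    gene_density,
    pervasiveness,
    scaling_analysis,
    summarize_domain,
    venn_high_pervasiveness,
)

from conftest import make_census, make_meta, random_cohort

# ---------------------------------------------------------------- oracles


def welch_oracle(x, y):
    """Closed-form Welch t with Satterthwaite df; p via scipy.special only."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * special.stdtr(df, -abs(t))
    return t, p


def mwu_exact_oracle(x, y):
    """Full enumeration of all C(nx+ny, nx) group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)

    def u_of(assignment):
        xs = [pooled[i] for i in assignment]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(assignment)]
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    u_obs = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in x for b in y)
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), nx)]
    n = len(us)
    # two-sided: double the smaller tail (scipy's exact convention, no ties)
    p_ge = sum(1 for u in us if u >= u_obs) / n
    p_le = sum(1 for u in us if u <= u_obs) / n
    return u_obs, min(1.0, 2 * min(p_ge, p_le))


def mwu_asymptotic_oracle(x, y):
    """Normal approximation with tie correction and continuity correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    order = pooled.argsort()
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    for v in np.unique(pooled):
        mask = pooled == v
        ranks[mask] = ranks[mask].mean()
    u = ranks[:nx].sum() - nx * (nx + 1) / 2
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = nx * ny / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = nx * ny / 2
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var) if u != mu else 0.0
    return u, min(1.0, 2 * special.ndtr(-abs(z)))


def classify_oracle(euk, arc, bac, high=0.70, low=0.30):
    """Independently coded rule evaluator for the Greek groups."""
    if euk > high and arc > high and bac > high:
        return "alpha"
    if euk > high and arc > high and bac <= low:
        return "beta"
    if arc > high and bac > high and euk <= low:
        return "gamma"
    if euk > high and arc <= low and bac <= low:
        return "delta"
    if max(euk, arc, bac) <= low:
        return "epsilon"
    return "other"


# ------------------------------------------------------------- summaries


def test_summary_closed_form_on_tiny_sample():
    cs = [make_census(f"g{i}", {("Met", "CAT"): k}) for i, k in enumerate((1, 2, 3))]
    metas = [make_meta(f"g{i}", "Bacteria") for i in range(3)]
    df = summarize_domain(cs, metas, metrics=("total_trna",))
    row = df.iloc[0]
    assert row["mean"] == 2 and row["median"] == 2
    assert row["sd"] == pytest.approx(1.0)
    assert row["se"] == pytest.approx(1 / math.sqrt(3))
    assert row["iqr"] == pytest.approx(1.0)  # linear-interpolation quantiles


def test_single_genome_domain_reports_missing_sd_not_zero():
    cs = [make_census("g0", {("Met", "CAT"): 5})]
    metas = [make_meta("g0", "Archaea")]
    df = summarize_domain(cs, metas, metrics=("total_trna",))
    assert math.isnan(df.iloc[0]["sd"]) and math.isnan(df.iloc[0]["se"])


def test_generator_parameter_recovery_for_mean_cn():
    """Cohort generated at a known mean CN is recovered within 3 SE."""
    from trnaome.profiles import default_profiles
    from trnaome.simulate import generate_genome
    from trnaome.census import build_census

    target = 400.0
    prof = default_profiles()["Eukarya"].with_overrides(
        genome_size_range_mb=(2000.0, 2000.001), cn_scaling=(0.2, 1.0, 0.0)
    )  # deterministic CN = 0.2 * 2000 = 400
    rng = np.random.default_rng(5)
    cs, metas = [], []
    for i in range(40):
        loci, meta = generate_genome(f"e{i}", prof, rng)
        cs.append(build_census(loci, f"e{i}"))
        metas.append(meta)
    df = summarize_domain(cs, metas, metrics=("total_trna",))
    row = df.iloc[0]
    assert abs(row["mean"] - target) <= max(3 * row["se"], 1.0)


# --------------------------------------------------------- pervasiveness


def test_pervasiveness_simple_fraction():
    combo = {("Leu", "TAA"): 1}
    cs = [make_census(f"b{i}", combo if i < 2 else {("Met", "CAT"): 1}) for i in range(4)]
    cs += [make_census("e0", combo), make_census("a0", combo)]
    metas = [make_meta(f"b{i}", "Bacteria") for i in range(4)]
    metas += [make_meta("e0", "Eukarya"), make_meta("a0", "Archaea")]
    pm = pervasiveness(cs, metas)
    assert pm.fraction.loc[("Leu", "TAA"), "Bacteria"] == 0.5
    assert pm.fraction.loc[("Leu", "TAA"), "Eukarya"] == 1.0
    assert pm.n_genomes["Bacteria"] == 4


def test_pervasiveness_errors_on_empty_domain():
    cs = [make_census("g0", {("Met", "CAT"): 1})]
    metas = [make_meta("g0", "Bacteria")]
    with pytest.raises(ValueError, match="Eukarya|Archaea"):
        pervasiveness(cs, metas)


def test_pervasiveness_matches_brute_force_and_is_order_invariant():
    rng = np.random.default_rng(123)
    cs, metas = random_cohort(rng)
    pm = pervasiveness(cs, metas)
    dom = {m.genome_id: m.domain for m in metas}
    for combo in pm.combinations:
        for d in ("Eukarya", "Archaea", "Bacteria"):
            members = [c for c in cs if dom[c.genome_id] == d]
            frac = sum(
                1 for c in members if c.counts_by_combination.get(combo, 0) >= 1
            ) / len(members)
            mean_cn = np.mean([c.counts_by_combination.get(combo, 0) for c in members])
            assert pm.fraction.loc[combo, d] == pytest.approx(frac)
            assert pm.mean_cn.loc[combo, d] == pytest.approx(mean_cn)
            assert 0 <= pm.fraction.loc[combo, d] <= 1
    pm2 = pervasiveness(list(reversed(cs)), metas)
    assert pm.fraction.equals(pm2.fraction)


# ------------------------------------------------------------ the groups


@pytest.mark.parametrize(
    "cells,label",
    [
        ((0.9, 0.8, 0.75), "alpha"),
        ((0.95, 0.85, 0.05), "beta"),
        ((0.05, 0.85, 0.95), "gamma"),
        ((0.95, 0.05, 0.05), "delta"),
        ((0.1, 0.1, 0.1), "epsilon"),
        ((0.9, 0.5, 0.9), "other"),
    ],
)
def test_group_rule_examples(cells, label):
    cs, metas = [], []
    # single combination; realize target pervasiveness with 20 genomes/domain
    for d, frac in zip(("Eukarya", "Archaea", "Bacteria"), cells):
        k = round(frac * 20)
        for i in range(20):
            gid = f"{d[:1]}{i}"
            combo = {("Leu", "TAA"): 1} if i < k else {("Met", "CAT"): 1}
            cs.append(make_census(gid, combo))
            metas.append(make_meta(gid, d))
    pm = pervasiveness(cs, metas)
    assert classify_groups(pm)[("Leu", "TAA")] == label


def test_group_classification_matches_oracle_on_random_matrices():
    import pandas as pd
    from trnaome.comparative import PervasivenessMatrix

    rng = np.random.default_rng(99)
    for _ in range(200):
        combos = [("Xxx", f"c{i}") for i in range(8)]
        idx = pd.MultiIndex.from_tuples(combos)
        cells = rng.random((8, 3))
        pm = PervasivenessMatrix(
            fraction=pd.DataFrame(cells, index=idx, columns=["Eukarya", "Archaea", "Bacteria"]),
            mean_cn=pd.DataFrame(0.0, index=idx, columns=["Eukarya", "Archaea", "Bacteria"]),
            n_genomes=None,
        )
        labels = classify_groups(pm)
        for combo, (e, a, b) in zip(combos, cells):
            assert labels[combo] == classify_oracle(e, a, b)
        assert set(labels) == set(combos)  # exhaustive, one label each


def test_group_thresholds_validated():
    rng = np.random.default_rng(1)
    cs, metas = random_cohort(rng)
    pm = pervasiveness(cs, metas)
    with pytest.raises(ValueError):
        classify_groups(pm, high=0.3, low=0.7)


# ------------------------------------------------------------------ venn


def _venn_oracle(sets):
    doms = list(sets)
    regions = {}
    for r in range(1, 4):
        for inside in itertools.combinations(doms, r):
            outside = [d for d in doms if d not in inside]
            members = set.intersection(*(sets[d] for d in inside))
            for d in outside:
                members -= sets[d]
            regions[frozenset(inside)] = len(members)
    return regions


def test_venn_identical_and_disjoint_sets():
    import pandas as pd
    from trnaome.comparative import PervasivenessMatrix

    combos = [("Xxx", f"c{i}") for i in range(26)]
    idx = pd.MultiIndex.from_tuples(combos)
    doms = ["Eukarya", "Archaea", "Bacteria"]
    pm = PervasivenessMatrix(
        fraction=pd.DataFrame(0.9, index=idx, columns=doms),
        mean_cn=pd.DataFrame(0.0, index=idx, columns=doms),
        n_genomes=None,
    )
    regions = venn_high_pervasiveness(pm)
    assert regions[frozenset(doms)] == 26
    assert sum(regions.values()) == 26

    cells = np.zeros((3, 3))
    np.fill_diagonal(cells, 0.9)
    idx3 = pd.MultiIndex.from_tuples([("Xxx", "a"), ("Xxx", "b"), ("Xxx", "c")])
    pm = PervasivenessMatrix(
        fraction=pd.DataFrame(cells, index=idx3, columns=doms),
        mean_cn=pd.DataFrame(0.0, index=idx3, columns=doms),
        n_genomes=None,
    )
    regions = venn_high_pervasiveness(pm)
    for d in doms:
        assert regions[frozenset([d])] == 1
    assert regions[frozenset(doms)] == 0


def test_venn_matches_set_algebra_on_random_cohorts():
    rng = np.random.default_rng(77)
    for _ in range(20):
        cs, metas = random_cohort(rng)
        pm = pervasiveness(cs, metas)
        regions = venn_high_pervasiveness(pm, threshold=0.5)
        sets = {
            d: {c for c in pm.combinations if pm.fraction.loc[c, d] > 0.5}
            for d in pm.fraction.columns
        }
        assert regions == _venn_oracle(sets)
        union = set().union(*sets.values())
        assert sum(regions.values()) == len(union)
        assert all(v >= 0 for v in regions.values())


# --------------------------------------------------------------- density


def test_density_division_and_inverse_identity():
    cs = [make_census("z", {("Met", "CAT"): 60})]
    metas = [make_meta("z", "Bacteria", size_mb=3.0)]
    df = gene_density(metas, cs)
    assert df.iloc[0]["trna_density"] == pytest.approx(20.0)
    assert df.iloc[0]["trna_density"] * 3.0 == pytest.approx(60)


def test_density_large_genome_example():
    # a zebrafish-sized case: 10,471 loci in a 1,500 Mb genome ≈ 7 per Mb
    cs = [make_census("fish", {("Met", "CAT"): 10471})]
    metas = [make_meta("fish", "Eukarya", size_mb=1500.0)]
    df = gene_density(metas, cs)
    assert df.iloc[0]["trna_density"] == pytest.approx(6.98, abs=0.01)


# ------------------------------------------------------------ group tests


def test_identical_samples_symmetry():
    x = [1.0, 2.0, 3.0, 4.0]
    res = compare_groups(x, x)
    t, p = res["welch_t"]
    assert t == pytest.approx(0.0) and p == pytest.approx(1.0)
    u, _ = res["mann_whitney"]
    assert u == pytest.approx(len(x) ** 2 / 2)


def test_separated_samples_exact_u():
    res = compare_groups([1, 2, 3, 4], [10, 11, 12, 13])
    u, p = res["mann_whitney"]
    assert u == 0.0
    assert p == pytest.approx(2 / 70)  # doubled one-sided exact 1/70


def test_welch_matches_oracle_on_random_unequal_variance_pairs():
    rng = np.random.default_rng(2024)
    for _ in range(50):
        x = rng.normal(0, 1, int(rng.integers(5, 40)))
        y = rng.normal(0.5, 3, int(rng.integers(5, 40)))
        t, p = compare_groups(x, y)["welch_t"]
        t0, p0 = welch_oracle(x, y)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)


def test_mwu_exact_matches_enumeration():
    rng = np.random.default_rng(8)
    for _ in range(10):
        x = rng.permutation(100)[: int(rng.integers(3, 7))].astype(float)
        y = rng.permutation(100)[:5].astype(float) + 0.5  # no ties with x
        u, p = compare_groups(x, y)["mann_whitney"]
        u0, p0 = mwu_exact_oracle(x, y)
        assert u == pytest.approx(u0)
        assert p == pytest.approx(p0, abs=1e-10)


def test_mwu_asymptotic_matches_tie_corrected_normal_approximation():
    rng = np.random.default_rng(31)
    for _ in range(50):
        x = rng.integers(0, 15, int(rng.integers(25, 60))).astype(float)
        y = rng.integers(3, 18, int(rng.integers(25, 60))).astype(float)
        u, p = compare_groups(x, y)["mann_whitney"]
        u0, p0 = mwu_asymptotic_oracle(x, y)
        assert u == pytest.approx(u0)
        assert p == pytest.approx(p0, abs=1e-10)


def test_swapping_samples_negates_t_and_reflects_u():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 12)
    y = rng.normal(1, 2, 15)
    fwd, rev = compare_groups(x, y), compare_groups(y, x)
    assert fwd["welch_t"][0] == pytest.approx(-rev["welch_t"][0])
    assert fwd["welch_t"][1] == pytest.approx(rev["welch_t"][1])
    assert fwd["mann_whitney"][0] == pytest.approx(
        len(x) * len(y) - rev["mann_whitney"][0]
    )
    assert 0 <= fwd["welch_t"][1] <= 1 and 0 <= fwd["mann_whitney"][1] <= 1


def test_zero_variance_raises_not_nan():
    with pytest.raises(ValueError, match="zero variance"):
        compare_groups([3.0, 3.0, 3.0], [5.0, 5.0, 5.0])


# --------------------------------------------------------------- scaling


def test_noiseless_power_law_recovered_exactly():
    b = 0.73
    sizes = np.logspace(0, 3, 30)
    cs = [make_census(f"g{i}", {("Met", "CAT"): 1}) for i in range(30)]
    # overwrite totals to follow CN = 2 * size^b exactly
    for i, c in enumerate(cs):
        c.total_trna = 2 * sizes[i] ** b
    metas = [make_meta(f"g{i}", "Bacteria", size_mb=float(sizes[i])) for i in range(30)]
    df = scaling_analysis(metas, cs, variables=("genome_size_mb", "total_trna"))
    row = df[df.scope == "all"].iloc[0]
    assert row["loglog_slope"] == pytest.approx(b, abs=1e-6)
    assert row["spearman_rho"] == pytest.approx(1.0)


def test_constant_cn_gives_zero_correlation_and_slope():
    cs = [make_census(f"g{i}", {("Met", "CAT"): 50}) for i in range(10)]
    metas = [make_meta(f"g{i}", "Bacteria", size_mb=float(i + 1)) for i in range(10)]
    df = scaling_analysis(metas, cs, variables=("genome_size_mb", "total_trna"))
    row = df[df.scope == "all"].iloc[0]
    assert row["spearman_rho"] == 0.0
    assert row["loglog_slope"] == pytest.approx(0.0, abs=1e-12)


def test_generator_scaling_exponent_recovered_within_ci():
    from trnaome.profiles import default_profiles
    from trnaome.simulate import generate_genome
    from trnaome.census import build_census

    # size range kept above ~1 Gb so the CN floor (repertoire size) never binds
    prof = default_profiles()["Eukarya"].with_overrides(
        cn_scaling=(0.2, 1.0, 0.3), genome_size_range_mb=(1000.0, 100000.0)
    )
    rng = np.random.default_rng(17)
    cs, metas = [], []
    for i in range(120):
        loci, meta = generate_genome(f"e{i}", prof, rng)
        cs.append(build_census(loci, f"e{i}"))
        metas.append(meta)
    df = scaling_analysis(metas, cs, variables=("genome_size_mb", "total_trna"))
    slope = df[df.scope == "all"].iloc[0]["loglog_slope"]
    # lognormal noise sd 0.3 over 4 decades of size: slope within ~0.05
    assert slope == pytest.approx(1.0, abs=0.1)
    assert df[df.scope == "all"].iloc[0]["spearman_rho"] > 0.9
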