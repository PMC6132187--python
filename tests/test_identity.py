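"""Variant/sample QC, sex and ancestry imputation, kinship estimator."""

import numpy as np
import pandas as pd
import pytest

from oracles import hwe_exact_oracle, kinship_loop

from omicsqc import identity, synthetic
from omicsqc.containers import GenotypeMatrix


def _make_genotypes(dosage: np.ndarray, chroms=None, sample_meta=None):
    n_samples, n_variants = dosage.shape
    chroms = chroms or ["1"] * n_variants
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.arange(1, n_variants + 1) * 1000,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index([f"v{i}" for i in range(n_variants)], name="variant"),
    )
    samples = pd.DataFrame(index=pd.Index([f"s{i}" for i in range(n_samples)],
                                          name="sample_id"))
    if sample_meta:
        for k, v in sample_meta.items():
            samples[k] = v
    return GenotypeMatrix(
        pd.DataFrame(dosage, index=samples.index, columns=variants.index),
        variants,
        samples,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def test_hwe_monomorphic_is_one():
    assert identity.hwe_exact_test(25, 0, 0) == 1.0
    assert identity.hwe_exact_test(0, 0, 12) == 1.0


def test_hwe_matches_enumeration_oracle_on_random_counts():
    rng = np.random.default_rng(0)
    cases = [(0, 2, 0), (1, 1, 1), (5, 0, 5), (10, 25, 15)]
    for _ in range(300):
        n = int(rng.integers(1, 51))
        n_aa = int(rng.integers(0, n + 1))
        n_ab = int(rng.integers(0, n - n_aa + 1))
        cases.append((n_aa, n_ab, n - n_aa - n_ab))
    for n_AA, n_Aa, n_aa in cases:
        got = identity.hwe_exact_test(n_AA, n_Aa, n_aa)
        want = hwe_exact_oracle(n_AA, n_Aa, n_aa)
        assert got == pytest.approx(want, abs=1e-12), (n_AA, n_Aa, n_aa)


def test_hwe_rejects_bad_counts():
    with pytest.raises(ValueError):
        identity.hwe_exact_test(-1, 0, 3)
    with pytest.raises(ValueError):
        identity.hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

def test_variant_qc_rules_and_boundaries():
    rng = np.random.default_rng(1)
    n = 100
    cols = []
    # v0, v1: fail missing rate (51% missing)
    for _ in range(2):
        c = rng.binomial(2, 0.4, n).astype(float)
        c[: 51] = np.nan
        cols.append(c)
    # v2, v3: fail MAF (one alt allele in 200)
    for _ in range(2):
        c = np.zeros(n)
        c[0] = 1.0
        cols.append(c)
    # v4, v5: fail HWE (every sample heterozygous)
    for _ in range(2):
        cols.append(np.ones(n))
    # v6..v9: pass, Hardy-Weinberg draws at p=0.4
    for _ in range(4):
        cols.append(rng.binomial(2, 0.4, n).astype(float))
    g = _make_genotypes(np.column_stack(cols))
    filtered, report = identity.variant_qc(g)
    assert list(filtered.variants.index) == ["v6", "v7", "v8", "v9"]
    assert set(report.loc[["v0", "v1"], "fail_reason"]) == {"missing_rate"}
    assert set(report.loc[["v2", "v3"], "fail_reason"]) == {"maf"}
    assert set(report.loc[["v4", "v5"], "fail_reason"]) == {"hwe"}

    # boundaries are strict: exactly 50% missing and exactly MAF 0.01 pass
    b1 = rng.binomial(2, 0.4, n).astype(float)
    b1[:50] = np.nan
    b2 = np.zeros(n)
    b2[0] = 2.0  # 2 alt alleles / 200 = MAF 0.01
    gb = _make_genotypes(np.column_stack([b1, b2, rng.binomial(2, .5, n).astype(float)]))
    fb, _ = identity.variant_qc(gb)
    assert {"v0", "v1"} <= set(fb.variants.index)

    # HWE is not applied to X variants
    x_het = np.ones(n)
    gx = _make_genotypes(
        np.column_stack([x_het, rng.binomial(2, 0.5, n).astype(float)]),
        chroms=["X", "1"],
    )
    fx, _ = identity.variant_qc(gx)
    assert "v0" in set(fx.variants.index)

    with pytest.raises(identity.EmptyFilterError):
        identity.variant_qc(_make_genotypes(np.ones((n, 2))))


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def test_heterozygosity_outliers_flag_contamination():
    rng = np.random.default_rng(2)
    p = rng.uniform(0.2, 0.8, 800)
    dosage = rng.binomial(2, p, size=(100, 800)).astype(float)
    # sample 0 "contaminated": heterozygous at 85% of loci
    dosage[0] = np.where(rng.random(800) < 0.85, 1.0, 0.0)
    g = _make_genotypes(dosage)
    out = identity.heterozygosity_outliers(g)
    assert bool(out.loc["s0", "flagged"])
    assert out["flagged"].sum() == 1

    # permutation invariance
    perm = rng.permutation(800)
    gp = g.subset_variants(g.variants.index[perm])
    assert identity.heterozygosity_outliers(gp)["flagged"].equals(out["flagged"])


def test_heterozygosity_zero_spread_warns_no_flags():
    dosage = np.tile(np.array([0.0, 1.0] * 10), (12, 1))
    with pytest.warns(UserWarning):
        out = identity.heterozygosity_outliers(_make_genotypes(dosage))
    assert not out["flagged"].any()


# ---------------------------------------------------------------------------
# Sex imputation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def sex_cohort():
    """Error-free single-modality cohort with 800 X variants: enough loci
    that the female F distribution concentrates well inside (-0.2, 0.2)."""
    cfg = synthetic.CohortConfig(
        n_brains=100,
        n_autosomal_variants=200,
        n_x_variants=800,
        modalities=[("WGS", 1.0, 0.0, 0.0)],
        rng_seed=12,
    )
    return synthetic.generate_genotypes(cfg)


def test_sex_from_x_inbreeding(sex_cohort):
    g, _ = sex_cohort
    res = identity.impute_sex_genotype(g)
    males = g.samples["sex"] == "male"
    # hemizygous males are perfectly homozygous on X
    assert np.allclose(res.loc[males, "F"], 1.0)
    # females at Hardy-Weinberg sit near F = 0
    assert (res.loc[~males, "F"].abs() < 0.2).all()
    assert (res["sex_call"] == g.samples["sex"]).all()
    assert not res["mismatch"].any()


def test_sex_mislabels_flagged_exactly(sex_cohort):
    g, truth = sex_cohort
    g = g.copy()
    rng = np.random.default_rng(3)
    flipped = list(rng.choice(g.samples.index, size=6, replace=False))
    for s in flipped:
        g.samples.loc[s, "sex"] = (
            "male" if g.samples.loc[s, "sex"] == "female" else "female"
        )
    res = identity.impute_sex_genotype(g)
    assert sorted(res.index[res["mismatch"]]) == sorted(flipped)


def test_sex_from_expression_clean_ambiguous_and_invariance():
    sexes = ["female"] * 30 + ["male"] * 30
    ids = [f"s{i}" for i in range(60)]
    markers, amb = synthetic.generate_sex_markers(ids, sexes, 0.0, rng_seed=4)
    calls = identity.impute_sex_expression(markers)
    assert (calls == pd.Series(sexes, index=ids)).all()

    markers2, amb2 = synthetic.generate_sex_markers(ids, sexes, 0.1, rng_seed=5)
    calls2 = identity.impute_sex_expression(markers2)
    assert len(amb2) == 6
    assert (calls2[amb2] == "ambiguous").all()

    # monotone transforms that preserve the dominant gap do not change calls
    for f in (lambda v: 3 * v + 7, np.log1p, np.sqrt):
        transformed = markers.values.apply(f)
        assert identity.impute_sex_expression(transformed).equals(calls)


def test_sex_expression_degenerate_axis_all_ambiguous():
    sexes = ["female"] * 40
    ids = [f"s{i}" for i in range(40)]
    markers, _ = synthetic.generate_sex_markers(ids, sexes, 0.0, rng_seed=6)
    with pytest.warns(UserWarning):
        calls = identity.impute_sex_expression(markers)
    assert (calls == "ambiguous").all()


# ---------------------------------------------------------------------------
# PCA / ancestry
# ---------------------------------------------------------------------------

def test_ancestry_mismatches_flagged_across_seeds():
    """Two populations at divergence 0.1; 4 injected race mislabels are all
    flagged with zero false flags, across 10 seeds."""
    for seed in range(10):
        cfg = synthetic.CohortConfig(
            n_brains=75,
            n_autosomal_variants=1500,
            n_x_variants=0,
            populations=[("EUR", 0.6, 0.1), ("AFR", 0.4, 0.1)],
            modalities=[("WGS", 1.0, 0.0, 0.0)],
            rng_seed=seed,
        )
        g, truth = synthetic.generate_genotypes(cfg)
        plan = synthetic.plan_corruptions(
            g, n_race=4, rng=np.random.default_rng(seed + 50)
        )
        gc, truth = synthetic.inject_label_errors(g, truth, plan)
        pcs, ev = identity.genotype_pca(gc)
        assert ev[0] >= ev[1]
        res = identity.ancestry_check(pcs, gc.samples["race"])
        bad = {c["sample"] for c in truth.corruptions if c["kind"] == "race_mislabel"}
        flagged = set(res.index[res["status"] == "mismatch"])
        assert flagged == bad, f"seed {seed}: {flagged} != {bad}"


def test_ancestry_no_structure_no_mismatch():
    cfg = synthetic.CohortConfig(
        n_brains=60,
        n_autosomal_variants=1000,
        n_x_variants=0,
        populations=[("EUR", 0.5, 0.0), ("AFR", 0.5, 0.0)],
        modalities=[("WGS", 1.0, 0.0, 0.0)],
        rng_seed=1,
    )
    g, _ = synthetic.generate_genotypes(cfg)
    pcs, _ = identity.genotype_pca(g)
    res = identity.ancestry_check(pcs, g.samples["race"])
    assert (res["status"] != "mismatch").all()


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def test_kinship_self_is_half_and_symmetric():
    rng = np.random.default_rng(7)
    x = rng.binomial(2, rng.uniform(0.05, 0.95, 1000)).astype(float)
    assert identity.kinship(x, x) == 0.5
    y = rng.binomial(2, rng.uniform(0.05, 0.95, 1000)).astype(float)
    assert identity.kinship(x, y) == identity.kinship(y, x)


def test_kinship_allele_flip_invariance():
    rng = np.random.default_rng(8)
    x = rng.binomial(2, 0.5, 2000).astype(float)
    y = rng.binomial(2, 0.5, 2000).astype(float)
    flip = rng.random(2000) < 0.5
    xf, yf = x.copy(), y.copy()
    xf[flip] = 2 - xf[flip]
    yf[flip] = 2 - yf[flip]
    assert identity.kinship(x, y) == pytest.approx(identity.kinship(xf, yf))


def test_kinship_unrelated_and_parent_offspring():
    rng = np.random.default_rng(9)
    p = rng.uniform(0.05, 0.95, 5000)
    phis, phis_po = [], []
    for _ in range(60):
        a = rng.binomial(2, p).astype(float)
        b = rng.binomial(2, p).astype(float)
        phis.append(identity.kinship(a, b))
        # child: one allele transmitted from parent a, one from the population
        transmitted = np.where(a == 1, rng.binomial(1, 0.5, 5000), a / 2)
        child = transmitted + rng.binomial(1, p)
        phis_po.append(identity.kinship(a, child.astype(float)))
    assert abs(np.mean(phis)) < 0.02
    assert np.mean(phis_po) == pytest.approx(0.25, abs=0.03)


def test_kinship_undefined_without_heterozygotes():
    with pytest.warns(UserWarning):
        phi = identity.kinship(np.zeros(200), np.full(200, 2.0))
    assert np.isnan(phi)


def test_kinship_matrix_matches_pairwise_loop(small_cohort):
    g, _ = small_cohort
    sub = g.subset_samples(g.samples.index[:8])
    # punch some missingness in to exercise the shared-loci logic
    d = sub.dosage.copy()
    rng = np.random.default_rng(10)
    mask = rng.random(d.shape) < 0.05
    d[:] = np.where(mask, np.nan, d.to_numpy())
    sub = GenotypeMatrix(d, sub.variants, sub.samples)
    kin = identity.kinship_matrix(sub)
    auto = sub.autosomal()
    for i, si in enumerate(auto.samples.index):
        for sj in auto.samples.index[: i + 1]:
            want = kinship_loop(
                auto.dosage.loc[si].to_numpy(), auto.dosage.loc[sj].to_numpy()
            )
            assert kin.loc[si, sj] == pytest.approx(want, abs=1e-12)
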