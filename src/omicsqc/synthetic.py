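"""Synthetic multi-omics cohorts with known ground truth.

Every analysis stage of the pipeline is exercised on simulated cohorts that
emulate the structure of a postmortem-brain multi-omics study: several
hundred donor brains, each profiled by up to three sequencing modalities
(WGS / WES / RNA-seq variant calls) plus label-free proteomics, with

* population structure (Balding-Nichols allele-frequency divergence),
* sex-respecting X-chromosome genotypes (males hemizygous, coded {0,2}),
* per-modality genotype error and missingness,
* injected label errors (swaps, relabels, unknown ids, orphans, sex and
  race mislabels) recorded in a :class:`TruthLog`,
* batch-structured proteomics with the exponential MNAR mechanism
  P(M=1) = exp(-gamma0 - gamma1*y),
* sex-marker expression (XIST / DDX3Y / RPS4Y1) with an ambiguous fraction,
* genotype-driven protein levels for cis-pQTL sample matching.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    AbundanceMatrix,
    GenotypeMatrix,
    unknown_brain_sentinel,
)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Cohort-level genotype simulation settings.

    ``populations`` are (label, fraction of brains, Balding-Nichols
    divergence) triples; divergence 0 means allele frequencies identical to
    the ancestral pool.  ``modalities`` are (name, fraction of brains
    covered, per-genotype error rate, per-entry missing rate).
    """

    n_brains: int = 100
    n_autosomal_variants: int = 5000
    n_x_variants: int = 500
    populations: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("EUR", 0.80, 0.05),
            ("AFR", 0.12, 0.12),
            ("LAT", 0.08, 0.08),
        ]
    )
    modalities: list[tuple[str, float, float, float]] = field(
        default_factory=lambda: [
            ("WGS", 0.90, 0.002, 0.01),
            ("WES", 0.80, 0.005, 0.02),
            ("RNA", 0.95, 0.010, 0.05),
        ]
    )
    female_fraction: float = 0.65
    rng_seed: int = 0

    def validate(self):
        if self.n_brains < 1:
            raise ValueError("n_brains must be positive")
        if self.n_autosomal_variants + self.n_x_variants < 1:
            raise ValueError("at least one variant is required")
        total = sum(f for _, f, _ in self.populations)
        if not np.isclose(total, 1.0):
            raise ValueError("population fractions must sum to 1")
        for label, frac, fst in self.populations:
            if not 0 < frac <= 1:
                raise ValueError(f"population {label}: fraction must be in (0,1]")
            if fst < 0 or fst >= 1:
                raise ValueError(f"population {label}: divergence must be in [0,1)")
        for name, cov, err, miss in self.modalities:
            if not 0 < cov <= 1:
                raise ValueError(f"modality {name}: coverage must be in (0,1]")
            if not 0 <= err < 1 or not 0 <= miss < 1:
                raise ValueError(f"modality {name}: rates must be in [0,1)")


@dataclass
class ProteomicsSimConfig:
    """Mixed-effects proteomics simulation settings.

    Defaults emulate an 8-batch label-free experiment: per-protein mean
    abundances spread N(20, 2^2) on the log2-intensity scale, a reference
    standard offset alpha, batch-effect SD d = 0.8, residual SDs 0.2
    (reference) / 1.0 (regular, mostly donor biological variation) and an
    MNAR mechanism giving roughly 20%
    missingness at the centre of the abundance scale.  The final batch
    re-measures ``n_replicate_pairs`` samples of the previous batch as
    technical replicates.
    """

    n_proteins: int = 2000
    n_samples: int = 266  # regular samples, spread over n_batches - 1 batches
    n_batches: int = 8
    mu: float | np.ndarray | None = None  # default: N(20, 2^2) per protein
    alpha: float = 0.5
    d: float = 0.8
    sigma0: float = 0.2
    sigma: float = 1.0
    gamma0: float = -4.4
    gamma1: float = 0.3
    n_replicate_pairs: int = 18
    n_reference_per_batch: int = 3
    #: Fraction of a regular sample's residual variance sigma^2 that is the
    #: donor's biological deviation rather than measurement noise.  The two
    #: members of a technical replicate pair share the donor component (the
    #: same tissue homogenate was injected twice); every marginal
    #: distribution is unchanged.  Reference standards are a pooled
    #: homogenate, so their residual is pure measurement noise (sigma0).
    replicate_share: float = 0.9
    rng_seed: int = 0

    def validate(self):
        if min(self.d, self.sigma0, self.sigma) < 0:
            raise ValueError("d, sigma0 and sigma must be non-negative")
        if self.gamma1 < 0:
            raise ValueError("gamma1 must be non-negative")
        if self.n_batches < 2:
            raise ValueError("need at least 2 batches")
        per_batch = self.n_samples // (self.n_batches - 1)
        if self.n_replicate_pairs > per_batch:
            raise ValueError("more replicate pairs than donor-batch samples")
        if not 0.0 <= self.replicate_share <= 1.0:
            raise ValueError("replicate_share must be in [0, 1]")


@dataclass
class TruthLog:
    """Ground truth for a simulated cohort.

    ``samples`` is indexed by sequencing-sample id with the *true* brain,
    sex and population; ``corruptions`` records every injected label error
    as a dict with at least ``kind`` and ``sample`` keys.
    """

    samples: pd.DataFrame
    corruptions: list[dict] = field(default_factory=list)

    RECOVERABLE = ("swap", "brain_relabel", "id_unknown")

    def record(self, kind: str, sample: str, **details):
        self.corruptions.append({"kind": kind, "sample": sample, **details})

    def brain_corrupted_samples(self) -> set[str]:
        kinds = set(self.RECOVERABLE) | {"orphan"}
        return {c["sample"] for c in self.corruptions if c["kind"] in kinds}

    def recoverable_samples(self) -> set[str]:
        return {
            c["sample"] for c in self.corruptions if c["kind"] in self.RECOVERABLE
        }

    def unrecoverable_samples(self) -> set[str]:
        return {c["sample"] for c in self.corruptions if c["kind"] == "orphan"}

    def true_brain(self, sample: str) -> str:
        return self.samples.loc[sample, "brain_id"]


# ---------------------------------------------------------------------------
# Genotype cohort
# ---------------------------------------------------------------------------

def _balding_nichols(p_anc: np.ndarray, fst: float, rng) -> np.ndarray:
    """Population allele frequencies diverged from the ancestral pool."""
    if fst == 0:
        return p_anc.copy()
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)


def _draw_genotypes(p: np.ndarray, sex: str, is_x: np.ndarray, rng) -> np.ndarray:
    g = rng.binomial(2, p).astype(float)
    if sex == "male" and is_x.any():
        g[is_x] = 2.0 * rng.binomial(1, p[is_x])
    return g


def generate_genotypes(config: CohortConfig) -> tuple[GenotypeMatrix, TruthLog]:
    """Simulate per-modality genotype samples from shared donor brains.

    One latent diploid genotype is drawn per brain from its population's
    allele frequencies; each modality then observes an independent noisy,
    partially missing copy for the brains it covers.  X genotypes respect
    sex (males hemizygous, coded {0, 2}).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n_auto, n_x = config.n_autosomal_variants, config.n_x_variants
    n_var = n_auto + n_x

    # variant metadata
    chroms = np.concatenate(
        [
            np.array([str(1 + i % 22) for i in range(n_auto)]),
            np.array(["X"] * n_x),
        ]
    )
    pos = rng.integers(10_000, 240_000_000, size=n_var)
    refs = _BASES[rng.integers(0, 4, size=n_var)]
    alts = np.array(
        [_BASES[(list(_BASES).index(r) + rng.integers(1, 4)) % 4] for r in refs]
    )
    keys = [f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(chroms, pos, refs, alts)]
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": refs, "alt": alts},
        index=pd.Index(keys, name="variant"),
    )
    is_x = chroms == "X"

    # populations and their allele frequencies
    p_anc = rng.uniform(0.05, 0.95, size=n_var)
    pop_freqs = {
        label: _balding_nichols(p_anc, fst, rng)
        for label, _, fst in config.populations
    }
    labels = [label for label, _, _ in config.populations]
    fracs = np.array([f for _, f, _ in config.populations])

    # brains: population, sex, latent genotype
    brain_ids = [f"B{i:04d}" for i in range(config.n_brains)]
    brain_pop = rng.choice(labels, size=config.n_brains, p=fracs / fracs.sum())
    brain_sex = np.where(
        rng.random(config.n_brains) < config.female_fraction, "female", "male"
    )
    latent = {
        b: _draw_genotypes(pop_freqs[brain_pop[i]], brain_sex[i], is_x, rng)
        for i, b in enumerate(brain_ids)
    }

    # per-modality sample copies
    rows, meta = [], []
    for name, coverage, err, miss in config.modalities:
        n_cov = int(round(coverage * config.n_brains))
        covered = rng.choice(config.n_brains, size=n_cov, replace=False)
        for bi in sorted(covered):
            brain = brain_ids[bi]
            g = latent[brain].copy()
            if err > 0:
                flip = rng.random(n_var) < err
                if flip.any():
                    redraw = _draw_genotypes(
                        pop_freqs[brain_pop[bi]], brain_sex[bi], is_x, rng
                    )
                    g[flip] = redraw[flip]
            if miss > 0:
                g[rng.random(n_var) < miss] = np.nan
            sid = f"{name}_{brain}"
            rows.append(g)
            meta.append(
                {
                    "sample_id": sid,
                    "modality": name,
                    "brain_id": brain,
                    "sex": brain_sex[bi],
                    "race": brain_pop[bi],
                }
            )

    samples = pd.DataFrame(meta).set_index("sample_id")
    dosage = pd.DataFrame(
        np.vstack(rows), index=samples.index, columns=variants.index
    )
    gm = GenotypeMatrix(dosage, variants, samples)
    truth = TruthLog(
        samples=samples[["brain_id", "sex", "race"]].rename(
            columns={"race": "population"}
        ).copy()
    )
    return gm, truth


# ---------------------------------------------------------------------------
# Label-error injection
# ---------------------------------------------------------------------------

def inject_label_errors(
    g: GenotypeMatrix, truth: TruthLog, plan: list[dict]
) -> tuple[GenotypeMatrix, TruthLog]:
    """Apply a corruption plan to the *claimed* metadata.

    Supported request kinds (``{"kind": ..., ...}``):

    * ``swap``: ``samples=(a, b)`` -- exchange claimed brain ids,
    * ``brain_relabel``: ``sample, new_brain``,
    * ``id_unknown``: ``sample`` -- claimed brain replaced by a sentinel,
    * ``orphan``: ``sample, new_brain`` -- relabel constructed so the true
      identity is unrecoverable (the true brain has no other sample),
    * ``sex_mislabel``: ``sample`` -- claimed sex flipped,
    * ``race_mislabel``: ``sample, new_race``.

    Genotypes are never touched; the TruthLog records what was done.  A
    sample may receive at most one brain-identity corruption.
    """
    g = g.copy()
    brain_kinds = {"swap", "brain_relabel", "id_unknown", "orphan"}
    seen: set[str] = set(truth.brain_corrupted_samples())
    for req in plan:
        kind = req["kind"]
        targets = list(req["samples"]) if kind == "swap" else [req["sample"]]
        for s in targets:
            if s not in g.samples.index:
                raise ValueError(f"unknown sample in corruption plan: {s}")
        if kind in brain_kinds:
            for s in targets:
                if s in seen:
                    raise ValueError(
                        f"sample {s} already has a brain-identity corruption"
                    )
                seen.add(s)

        if kind == "swap":
            a, b = targets
            ba, bb = g.samples.loc[a, "brain_id"], g.samples.loc[b, "brain_id"]
            if ba == bb:
                raise ValueError("swap between samples of the same brain is a no-op")
            g.samples.loc[a, "brain_id"], g.samples.loc[b, "brain_id"] = bb, ba
            truth.record("swap", a, partner=b, claimed=bb)
            truth.record("swap", b, partner=a, claimed=ba)
        elif kind == "brain_relabel":
            s, nb = targets[0], req["new_brain"]
            if nb == g.samples.loc[s, "brain_id"]:
                raise ValueError("relabel target equals the true brain")
            g.samples.loc[s, "brain_id"] = nb
            truth.record("brain_relabel", s, claimed=nb)
        elif kind == "id_unknown":
            s = targets[0]
            g.samples.loc[s, "brain_id"] = unknown_brain_sentinel(s)
            truth.record("id_unknown", s)
        elif kind == "orphan":
            s, nb = targets[0], req["new_brain"]
            if nb == g.samples.loc[s, "brain_id"]:
                raise ValueError("orphan target equals the true brain")
            g.samples.loc[s, "brain_id"] = nb
            truth.record("orphan", s, claimed=nb)
        elif kind == "sex_mislabel":
            s = targets[0]
            cur = g.samples.loc[s, "sex"]
            g.samples.loc[s, "sex"] = "male" if cur == "female" else "female"
            truth.record("sex_mislabel", s, claimed=g.samples.loc[s, "sex"])
        elif kind == "race_mislabel":
            s, nr = targets[0], req["new_race"]
            if nr == g.samples.loc[s, "race"]:
                raise ValueError("race relabel target equals the true race")
            g.samples.loc[s, "race"] = nr
            truth.record("race_mislabel", s, claimed=nr)
        else:
            raise ValueError(f"unknown corruption kind: {kind}")
    return g, truth


def plan_corruptions(
    g: GenotypeMatrix,
    *,
    n_swaps: int = 0,
    n_relabels: int = 0,
    n_unknown: int = 0,
    n_orphans: int = 0,
    n_sex: int = 0,
    n_race: int = 0,
    rng=None,
) -> list[dict]:
    """Draw a valid corruption plan against an uncorrupted cohort.

    Brain-identity corruptions are constructed to be *recoverable* (the
    sample's true brain keeps at least 2 other samples and brains are used
    by at most one corruption) except orphans, which are placed on
    single-sample brains and relabeled to a multi-sample brain so that no
    duplicate-level partner exists.  Raises when the cohort cannot host the
    requested plan.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    by_brain = g.samples.groupby("brain_id").groups
    sizes = {b: len(v) for b, v in by_brain.items()}
    multi = sorted(b for b, n in sizes.items() if n >= 3)
    single = sorted(b for b, n in sizes.items() if n == 1)
    rng.shuffle(multi)
    rng.shuffle(single)

    def take_multi(k):
        if len(multi) < k:
            raise ValueError("not enough multi-sample brains for the plan")
        return [multi.pop() for _ in range(k)]

    plan: list[dict] = []
    for _ in range(n_swaps):
        ba, bb = take_multi(2)
        a = str(rng.choice(sorted(by_brain[ba])))
        b = str(rng.choice(sorted(by_brain[bb])))
        plan.append({"kind": "swap", "samples": (a, b)})
    for _ in range(n_relabels):
        src, dst = take_multi(2)
        s = str(rng.choice(sorted(by_brain[src])))
        plan.append({"kind": "brain_relabel", "sample": s, "new_brain": dst})
    for _ in range(n_unknown):
        (src,) = take_multi(1)
        s = str(rng.choice(sorted(by_brain[src])))
        plan.append({"kind": "id_unknown", "sample": s})
    for _ in range(n_orphans):
        if not single:
            raise ValueError(
                "no single-sample brain available for an orphan corruption"
            )
        src = single.pop()
        (dst,) = take_multi(1)
        s = sorted(by_brain[src])[0]
        plan.append({"kind": "orphan", "sample": s, "new_brain": dst})

    untouched = sorted(
        set(g.samples.index)
        - {
            s
            for req in plan
            for s in (req["samples"] if req["kind"] == "swap" else [req["sample"]])
        }
    )
    rng.shuffle(untouched)
    races = sorted(g.samples["race"].unique())
    for _ in range(n_sex):
        plan.append({"kind": "sex_mislabel", "sample": untouched.pop()})
    for _ in range(n_race):
        s = untouched.pop()
        cur = g.samples.loc[s, "race"]
        others = [r for r in races if r != cur]
        plan.append(
            {"kind": "race_mislabel", "sample": s, "new_race": str(rng.choice(others))}
        )
    return plan


def score_resolution(actions, truth: TruthLog) -> dict:
    """Score an identity-resolution run against the ground truth.

    Returns counts of recoverable corruptions recovered (remapped/assigned
    to the true brain), unrecoverable samples excluded, plus any incorrect
    remaps or exclusions touching clean samples.
    """
    recoverable = truth.recoverable_samples()
    unrecoverable = truth.unrecoverable_samples()
    corrupted = truth.brain_corrupted_samples()
    by_sample = {a.sample: a for a in actions}

    recovered = sum(
        1
        for s in recoverable
        if s in by_sample
        and by_sample[s].action in ("remap", "assign")
        and by_sample[s].new_brain == truth.true_brain(s)
    )
    excluded_unrec = sum(
        1 for s in unrecoverable if s in by_sample and by_sample[s].action == "exclude"
    )
    false_remaps = sum(
        1
        for a in actions
        if a.action in ("remap", "assign")
        and (a.sample not in corrupted or a.new_brain != truth.true_brain(a.sample))
    )
    clean_excluded = sum(
        1 for a in actions if a.action == "exclude" and a.sample not in corrupted
    )
    return {
        "n_recoverable": len(recoverable),
        "recovered": recovered,
        "n_unrecoverable": len(unrecoverable),
        "excluded_unrecoverable": excluded_unrec,
        "false_remaps": false_remaps,
        "clean_excluded": clean_excluded,
    }


# ---------------------------------------------------------------------------
# Proteomics
# ---------------------------------------------------------------------------

@dataclass
class ProteomicsTruth:
    params: pd.DataFrame           # per-protein mu, alpha, d, sigma0, sigma
    gamma: tuple[float, float]
    batch_effects: pd.DataFrame    # proteins x batches
    complete: pd.DataFrame         # abundances before masking


def generate_proteomics(
    config: ProteomicsSimConfig,
) -> tuple[AbundanceMatrix, ProteomicsTruth]:
    """Simulate batch-structured proteomics with MNAR missingness.

    Regular samples fill batches 1..n_batches-1; the last batch re-measures
    ``n_replicate_pairs`` samples of the previous batch (independent batch
    effect and residuals, same protein means) plus reference standards.
    Every batch carries ``n_reference_per_batch`` reference injections.
    Missingness is Bernoulli with probability min(1, exp(-g0 - g1*y)).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    P = config.n_proteins
    nb = config.n_batches

    if config.mu is None:
        mu = rng.normal(20.0, 2.0, size=P)
    else:
        mu = np.broadcast_to(np.asarray(config.mu, dtype=float), (P,)).copy()

    # sample layout
    per_batch = config.n_samples // (nb - 1)
    extra = config.n_samples - per_batch * (nb - 1)
    meta = []
    k = 0
    donor_batch_samples: list[str] = []
    for b in range(1, nb):
        n_b = per_batch + (1 if b <= extra else 0)
        for _ in range(n_b):
            sid = f"S{k:04d}"
            meta.append({"sample_id": sid, "batch": f"b{b}", "is_reference": False})
            if b == nb - 1:
                donor_batch_samples.append(sid)
            k += 1
    replicate_pairs = []
    rep_sources = donor_batch_samples[: config.n_replicate_pairs]
    for sid in rep_sources:
        rep = f"{sid}_rep"
        meta.append({"sample_id": rep, "batch": f"b{nb}", "is_reference": False})
        replicate_pairs.append((sid, rep))
    for b in range(1, nb + 1):
        for j in range(config.n_reference_per_batch):
            meta.append(
                {
                    "sample_id": f"REF_b{b}_{j}",
                    "batch": f"b{b}",
                    "is_reference": True,
                }
            )
    samples = pd.DataFrame(meta).set_index("sample_id")
    batch_levels = [f"b{b}" for b in range(1, nb + 1)]
    batch_idx = pd.Categorical(
        samples["batch"], categories=batch_levels
    ).codes.astype(int)
    is_ref = samples["is_reference"].to_numpy(dtype=bool)

    # Residuals: regular samples split sigma^2 into a donor (biological)
    # component, shared between the two members of a replicate pair, and
    # independent measurement noise.  References are pure measurement noise.
    b_eff = rng.normal(0.0, config.d, size=(P, nb))
    sd_u = config.sigma * np.sqrt(config.replicate_share)
    sd_w = config.sigma * np.sqrt(1.0 - config.replicate_share)
    n_all = len(samples)
    u = rng.normal(0.0, 1.0, size=(P, n_all)) * sd_u
    w = rng.normal(0.0, 1.0, size=(P, n_all)) * sd_w
    col = {s: j for j, s in enumerate(samples.index)}
    for src, rep in replicate_pairs:
        u[:, col[rep]] = u[:, col[src]]
    e = np.where(is_ref[None, :], rng.normal(0.0, config.sigma0, (P, n_all)), u + w)
    y = (
        mu[:, None]
        + config.alpha * is_ref[None, :].astype(float)
        + b_eff[:, batch_idx]
        + e
    )

    prob = np.exp(-config.gamma0 - config.gamma1 * y)
    frac_sat = float((prob > 1).mean())
    if frac_sat > 0.01:
        warnings.warn(
            f"missingness mechanism saturates for {frac_sat:.1%} of entries; "
            "gamma0 is too small for this abundance scale"
        )
    mask = rng.random(y.shape) < np.minimum(prob, 1.0)

    proteins = pd.Index([f"P{i:05d}" for i in range(P)], name="protein")
    complete = pd.DataFrame(y, index=proteins, columns=samples.index)
    values = complete.mask(pd.DataFrame(mask, index=proteins, columns=samples.index))
    truth = ProteomicsTruth(
        params=pd.DataFrame(
            {
                "mu": mu,
                "alpha": config.alpha,
                "d": config.d,
                "sigma0": config.sigma0,
                "sigma": config.sigma,
            },
            index=proteins,
        ),
        gamma=(config.gamma0, config.gamma1),
        batch_effects=pd.DataFrame(b_eff, index=proteins, columns=batch_levels),
        complete=complete,
    )
    return (
        AbundanceMatrix(values, samples, replicate_pairs=replicate_pairs),
        truth,
    )


# ---------------------------------------------------------------------------
# Sex markers
# ---------------------------------------------------------------------------

def generate_sex_markers(
    sample_ids,
    true_sexes,
    ambiguous_fraction: float = 0.0,
    *,
    rng_seed: int = 0,
    high: float = 8.0,
    low: float = 1.0,
    spread: float = 0.4,
) -> tuple[AbundanceMatrix, list[str]]:
    """Simulate XIST / DDX3Y / RPS4Y1 expression for sex imputation.

    Females are high-XIST / low-male-marker, males the reverse; exactly
    ``round(ambiguous_fraction * n)`` samples are made high on *both* axes
    (the mixed-sample signature).  Returns the marker matrix and the list
    of ambiguous sample ids.
    """
    if not 0.0 <= ambiguous_fraction < 0.5:
        raise ValueError("ambiguous_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(rng_seed)
    ids = list(sample_ids)
    sexes = pd.Series(np.asarray(true_sexes, dtype=object), index=ids)
    n = len(ids)
    n_amb = int(round(ambiguous_fraction * n))
    amb = sorted(rng.choice(ids, size=n_amb, replace=False)) if n_amb else []

    female = (sexes == "female").to_numpy()
    xist = np.where(female, high, low) + rng.normal(0, spread, n)
    ddx3y = np.where(female, low, high) + rng.normal(0, spread, n)
    rps4y1 = np.where(female, low, high) + rng.normal(0, spread, n)
    if amb:
        pos = [ids.index(s) for s in amb]
        xist[pos] = high + rng.normal(0, spread, len(pos))
        ddx3y[pos] = high + rng.normal(0, spread, len(pos))
        rps4y1[pos] = high + rng.normal(0, spread, len(pos))

    values = pd.DataFrame(
        [xist, ddx3y, rps4y1],
        index=pd.Index(["XIST", "DDX3Y", "RPS4Y1"], name="gene"),
        columns=ids,
    )
    samples = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    samples["batch"] = "rnaseq"
    return AbundanceMatrix(values, samples), list(amb)


# ---------------------------------------------------------------------------
# cis-pQTL proteins
# ---------------------------------------------------------------------------

def generate_cis_pqtl_proteins(
    genotypes: GenotypeMatrix,
    n_proteins: int = 200,
    effect_size: float = 1.0,
    noise_sd: float = 0.5,
    *,
    rng_seed: int = 0,
    min_maf: float = 0.1,
    sample_prefix: str = "PROT",
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Genotype-driven protein abundances for sample-matching tests.

    Each protein is assigned one causal autosomal variant (MAF >=
    ``min_maf``); abundance for the proteomics copy of genotype sample s is
    ``beta0 + effect_size * dosage_s + N(0, noise_sd^2)``.  Protein
    coordinates are placed at the causal variant so cis windows contain it.
    Returns the abundance matrix (one proteomics sample per genotype
    sample, claimed brain id copied over) and the truth map
    (protein -> variant, beta0, beta).
    """
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    rng = np.random.default_rng(rng_seed)
    auto = genotypes.autosomal()
    maf = auto.maf()
    candidates = auto.variants.index[(maf >= min_maf).to_numpy()]
    if len(candidates) < n_proteins:
        raise ValueError(
            f"only {len(candidates)} variants with MAF >= {min_maf}; "
            f"cannot assign {n_proteins} causal variants"
        )
    causal = rng.choice(candidates, size=n_proteins, replace=False)
    beta0 = rng.normal(20.0, 2.0, size=n_proteins)

    d = auto.dosage[causal].to_numpy(dtype=float)  # samples x proteins
    p = np.nanmean(d, axis=0) / 2.0
    d_filled = np.where(np.isnan(d), 2.0 * p, d)
    y = beta0[None, :] + effect_size * d_filled
    y = y + rng.normal(0.0, noise_sd, size=y.shape)

    prot_ids = pd.Index([f"Q{i:04d}" for i in range(n_proteins)], name="protein")
    sample_ids = [f"{sample_prefix}_{s}" for s in genotypes.samples.index]
    values = pd.DataFrame(y.T, index=prot_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {
            "batch": "pqtl",
            "is_reference": False,
            "brain_id": genotypes.samples["brain_id"].to_numpy(),
            "genotype_sample": genotypes.samples.index.to_numpy(),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    features = pd.DataFrame(
        {
            "chrom": auto.variants.loc[causal, "chrom"].to_numpy(),
            "pos": auto.variants.loc[causal, "pos"].to_numpy(),
        },
        index=prot_ids,
    )
    truth_map = pd.DataFrame(
        {"variant": causal, "beta0": beta0, "beta": effect_size},
        index=prot_ids,
    )
    return AbundanceMatrix(values, samples, features=features), truth_map
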