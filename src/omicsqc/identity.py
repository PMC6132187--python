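"""Genotype-based sample QC and cross-modality identity resolution.

The central question this module answers is "does every sequencing sample
really come from the donor brain it is labeled with?".  Samples from the
same brain are genetic duplicates (kinship coefficient ~0.5), samples from
different, unrelated brains are not (kinship ~0), so pairwise kinship across
all modalities exposes swaps, relabels and contaminated samples.

The toolkit:

* variant-level filters (missing rate, minor allele frequency, Hardy-Weinberg
  exact test),
* per-sample heterozygosity outlier detection (contamination / inbreeding),
* sex imputation from the X-chromosome inbreeding coefficient and from
  sex-specific marker gene expression (XIST / DDX3Y / RPS4Y1),
* ancestry concordance from genotype principal components,
* the robust heterozygote-normalized kinship estimator,
* a concordance graph of suspicious (claimed-duplicate, kinship < 0.1) and
  spurious (claimed-unrelated, kinship > 0.354) pairs, and
* an iterative majority-voting procedure that remaps, assigns or excludes
  flagged samples until the graph is clean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import GenotypeMatrix, is_unknown_brain

#: Kinship above which a pair is treated as a duplicate / monozygotic twin.
DUPLICATE_KINSHIP = 0.354
#: Kinship below which a pair is at most 2nd-degree related ("distant").
DISTANT_KINSHIP = 0.1


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg equilibrium test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts as likely or less likely than the observed one.
    A monomorphic site returns p = 1.

    Parameters are genotype counts (hom-ref, het, hom-alt); ordering of the
    two homozygote classes does not affect the result.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped sample is required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0

    rare = min(n_A, n_a)
    # log P(h heterozygotes | allele counts); h has the parity of `rare`
    lg = math.lgamma

    def logp(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = (max(n_A, n_a) - h) // 2
        return (
            lg(n + 1)
            - lg(hom_rare + 1)
            - lg(h + 1)
            - lg(hom_common + 1)
            + h * math.log(2.0)
            + lg(n_A + 1)
            + lg(n_a + 1)
            - lg(2 * n + 1)
        )

    hs = range(rare % 2, rare + 1, 2)
    logps = {h: logp(h) for h in hs}
    obs = logps[n_Aa]
    # tolerate float noise when deciding "as or less likely"
    p = sum(math.exp(v) for v in logps.values() if v <= obs + 1e-12)
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Variant-level QC
# ---------------------------------------------------------------------------

class EmptyFilterError(ValueError):
    """All variants removed by QC; carries the per-variant report."""

    def __init__(self, message: str, report: pd.DataFrame):
        super().__init__(message)
        self.report = report


def variant_qc(
    g: GenotypeMatrix,
    *,
    max_missing: float = 0.5,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-3,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove variants with missing rate > 50%, MAF < 0.01 or HWE p < 0.001.

    Inequality senses are exactly as stated (strict on all three), so a
    variant sitting exactly on a boundary is retained.  The HWE test is run
    on autosomal variants only.  Returns the filtered matrix and a report
    with per-variant statistics and the failure reason (empty string for
    passing variants).
    """
    if g.n_samples < 1:
        raise ValueError("variant_qc requires at least one sample")
    miss = g.variant_missing_rate()
    maf = g.maf()
    auto = g.is_autosomal

    hwe_p = pd.Series(np.nan, index=g.variants.index)
    d = g.dosage.to_numpy()
    for j, key in enumerate(g.variants.index):
        if not auto.iloc[j]:
            continue
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            hwe_p.iloc[j] = 1.0
            continue
        hwe_p.iloc[j] = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )

    reasons = pd.Series("", index=g.variants.index)
    reasons[miss > max_missing] = "missing_rate"
    fail_maf = (maf < min_maf) & (reasons == "")
    reasons[fail_maf] = "maf"
    fail_hwe = auto & (hwe_p < hwe_alpha) & (reasons == "")
    reasons[fail_hwe] = "hwe"

    report = pd.DataFrame(
        {
            "missing_rate": miss,
            "maf": maf,
            "hwe_p": hwe_p,
            "fail_reason": reasons,
        }
    )
    keep = reasons == ""
    if not keep.any():
        raise EmptyFilterError("all variants removed by variant QC", report)
    return g.subset_variants(keep), report


# ---------------------------------------------------------------------------
# Sample-level statistics
# ---------------------------------------------------------------------------

def heterozygosity_outliers(
    g: GenotypeMatrix, *, z_threshold: float = 3.0
) -> pd.DataFrame:
    """Flag samples whose autosomal heterozygosity is > 3 SD from the mean.

    Excess heterozygosity suggests sample mixture (contamination); a deficit
    suggests inbreeding.  Returns per-sample ``het_rate``, ``z`` and
    ``flagged``.
    """
    auto = g.autosomal()
    if auto.n_samples < 10:
        warnings.warn("fewer than 10 samples; heterozygosity SD is unstable")
    d = auto.dosage.to_numpy()
    non_missing = (~np.isnan(d)).sum(axis=1)
    het = np.nansum(d == 1, axis=1)
    with np.errstate(invalid="ignore"):
        rate = np.where(non_missing > 0, het / non_missing, np.nan)
    mean, sd = np.nanmean(rate), np.nanstd(rate)
    if sd == 0 or np.isnan(sd):
        warnings.warn("zero heterozygosity spread; no outliers flagged")
        z = np.zeros_like(rate)
    else:
        z = (rate - mean) / sd
    return pd.DataFrame(
        {"het_rate": rate, "z": z, "flagged": np.abs(z) > z_threshold},
        index=g.samples.index,
    )


def impute_sex_genotype(
    g: GenotypeMatrix,
    *,
    male_threshold: float = 0.8,
    female_threshold: float = 0.2,
) -> pd.DataFrame:
    """Impute sex from the X-chromosome inbreeding coefficient F.

    For each sample, over its non-missing X loci,
    ``F = (O_hom - E_hom) / (L - E_hom)`` where ``O_hom`` is the observed
    homozygote count and ``E_hom = sum_l (1 - 2 p_l q_l)`` the count expected
    under Hardy-Weinberg with cohort allele frequencies.  Hemizygous males
    (coded {0,2}) give F = 1 exactly; females at Hardy-Weinberg give F ~ 0.
    Calls: male if F > ``male_threshold``, female if F < ``female_threshold``,
    else ambiguous.  A ``mismatch`` flag compares the call against the
    claimed ``sex`` column when present.
    """
    x = g.x_chromosome()
    d = x.dosage.to_numpy()
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 50:
        warnings.warn(
            f"only {int(poly.sum())} polymorphic X variants; "
            "genotype-based sex imputation is unreliable below ~50"
        )
    q = 1.0 - p
    e_hom_l = 1.0 - 2.0 * p * q  # per-locus expected homozygosity

    obs = ~np.isnan(d)
    L = obs.sum(axis=1).astype(float)
    o_hom = np.nansum((d != 1) & obs, axis=1).astype(float)
    e_hom = obs @ np.nan_to_num(e_hom_l)

    denom = L - e_hom
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(np.abs(denom) > 1e-9, (o_hom - e_hom) / denom, np.nan)

    call = np.full(len(F), "ambiguous", dtype=object)
    call[F > male_threshold] = "male"
    call[F < female_threshold] = "female"
    out = pd.DataFrame({"F": F, "sex_call": call}, index=g.samples.index)
    if "sex" in g.samples.columns:
        claimed = g.samples["sex"].astype(str)
        out["mismatch"] = (out["sex_call"] != "ambiguous") & (
            out["sex_call"] != claimed
        )
    return out


def _bimodal_split(values: np.ndarray) -> float | None:
    """Threshold separating two well-separated modes of a 1-D sample.

    Uses the largest gap between consecutive order statistics; the axis is
    declared unimodal (returns None) when that gap does not dominate the
    overall spread (gap <= range / 3) or there are too few points.
    """
    v = np.sort(values[~np.isnan(values)])
    if v.size < 4:
        return None
    gaps = np.diff(v)
    rng = v[-1] - v[0]
    if rng <= 0:
        return None
    i = int(np.argmax(gaps))
    if gaps[i] <= rng / 3.0:
        return None
    return float((v[i] + v[i + 1]) / 2.0)


FEMALE_MARKERS = ("XIST",)
MALE_MARKERS = ("DDX3Y", "RPS4Y1")


def impute_sex_expression(markers) -> pd.Series:
    """Call sex from marker-gene expression (XIST vs DDX3Y/RPS4Y1).

    ``markers`` is an :class:`AbundanceMatrix` or DataFrame whose rows
    include XIST and at least one male-specific marker.  Each axis (XIST;
    mean of male markers) is split into a low and a high mode; calls are by
    quadrant -- high-XIST/low-male = female, low/high = male, and both-high
    or both-low = ambiguous (both-high is the signature of a mixed sample).
    If either axis is unimodal every sample is called ambiguous.
    """
    values = markers.values if hasattr(markers, "samples") else markers
    if "XIST" not in values.index:
        raise ValueError("marker matrix must contain an XIST row")
    male_rows = [m for m in MALE_MARKERS if m in values.index]
    if not male_rows:
        raise ValueError("marker matrix must contain a male marker row")

    xist = values.loc["XIST"].to_numpy(dtype=float)
    male = values.loc[male_rows].mean(axis=0).to_numpy(dtype=float)

    tx = _bimodal_split(xist)
    tm = _bimodal_split(male)
    idx = values.columns
    if tx is None or tm is None:
        warnings.warn("degenerate one-cluster marker axis; all calls ambiguous")
        return pd.Series("ambiguous", index=idx, name="sex_call")

    hi_x, hi_m = xist > tx, male > tm
    call = np.full(len(idx), "ambiguous", dtype=object)
    call[hi_x & ~hi_m] = "female"
    call[~hi_x & hi_m] = "male"
    return pd.Series(call, index=idx, name="sex_call")


# ---------------------------------------------------------------------------
# Ancestry via genotype PCA
# ---------------------------------------------------------------------------

def genotype_pca(
    g: GenotypeMatrix, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA on mean-imputed, frequency-standardized autosomal dosages.

    Each variant is centred at 2p and scaled by sqrt(2p(1-p)); missing
    entries are imputed at the variant mean (zero after standardization).
    Returns (coordinates DataFrame with columns PC1..PCk, explained
    variances).
    """
    auto = g.autosomal()
    d = auto.dosage.to_numpy(dtype=float)
    p = np.nanmean(d, axis=0) / 2.0  # per-variant allele frequency
    keep = (p > 0) & (p < 1)
    d, p = d[:, keep], p[keep]
    x = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    x = np.nan_to_num(x, nan=0.0)
    k = min(n_components, min(x.shape) - 1)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=g.samples.index, columns=cols),
        pca.explained_variance_,
    )


def ancestry_check(
    pcs: pd.DataFrame,
    claimed: pd.Series,
    *,
    min_group: int = 3,
) -> pd.DataFrame:
    """Compare claimed population labels with nearest-centroid assignment.

    Centroids are computed per claimed label (groups with fewer than
    ``min_group`` members are dropped; their members are ambiguous) in the
    top-2 PC plane.  A sample is a ``mismatch`` when its nearest centroid
    differs from its claimed one, the margin (distance to claimed minus
    distance to assigned) exceeds half the distance between the two
    centroids, *and* those centroids are genuinely separated (inter-centroid
    distance larger than either group's within-group radial spread --
    without population structure the PCs carry no ancestry signal and no
    sample can be declared mislabeled); anything weaker yields
    ``ambiguous``.
    """
    xy = pcs[["PC1", "PC2"]]
    counts = claimed.value_counts()
    groups = [lbl for lbl in counts.index if counts[lbl] >= min_group]
    if len(groups) < 2:
        raise ValueError("ancestry check needs at least two labeled groups")
    centroids = {lbl: xy[claimed == lbl].mean(axis=0).to_numpy() for lbl in groups}
    spread = {
        lbl: float(
            np.linalg.norm(
                xy[claimed == lbl].to_numpy() - centroids[lbl], axis=1
            ).mean()
        )
        for lbl in groups
    }

    assigned, status = [], []
    for sid in xy.index:
        point = xy.loc[sid].to_numpy()
        dists = {lbl: float(np.linalg.norm(point - c)) for lbl, c in centroids.items()}
        best = min(dists, key=lambda l: (dists[l], l))
        assigned.append(best)
        lbl = claimed.loc[sid]
        if lbl not in centroids:
            status.append("ambiguous")
        elif best == lbl:
            status.append("match")
        else:
            margin = dists[lbl] - dists[best]
            sep = float(np.linalg.norm(centroids[best] - centroids[lbl]))
            separated = sep > max(spread[best], spread[lbl])
            status.append(
                "mismatch" if (separated and margin > sep / 2.0) else "ambiguous"
            )
    return pd.DataFrame(
        {"claimed": claimed, "assigned": assigned, "status": status},
        index=xy.index,
    )


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def kinship(gi: np.ndarray, gj: np.ndarray, *, min_overlap: int = 100) -> float:
    """Robust heterozygote-normalized kinship between two dosage vectors.

    phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j)) over loci non-missing
    in both samples, where N_Aa,Aa counts loci heterozygous in both,
    N_AA,aa loci with opposite homozygotes and N_Aa(.) heterozygous loci per
    sample.  Exactly 0.5 for identical vectors with at least one
    heterozygote; expectation 0 for unrelated samples; invariant to
    allele-label flips.  Returns NaN (with a warning) when neither sample
    has a heterozygous locus in the shared set.
    """
    gi = np.asarray(gi, dtype=float)
    gj = np.asarray(gj, dtype=float)
    both = ~np.isnan(gi) & ~np.isnan(gj)
    if both.sum() < min_overlap:
        warnings.warn(
            f"only {int(both.sum())} overlapping variants; kinship is noisy"
        )
    a, b = gi[both], gj[both]
    n11 = int(np.sum((a == 1) & (b == 1)))
    n02 = int(np.sum(np.abs(a - b) == 2))
    het_i = int(np.sum(a == 1))
    het_j = int(np.sum(b == 1))
    denom = het_i + het_j
    if denom == 0:
        warnings.warn("no heterozygous loci in shared set; kinship undefined")
        return float("nan")
    return (n11 - 2 * n02) / denom


def kinship_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """All-pairs robust kinship over autosomal variants (vectorized)."""
    d = g.autosomal().dosage.to_numpy(dtype=float)
    obs = ~np.isnan(d)
    H = ((d == 1) & obs).astype(float)
    A0 = ((d == 0) & obs).astype(float)
    A2 = ((d == 2) & obs).astype(float)
    V = obs.astype(float)

    n11 = H @ H.T
    n02 = A0 @ A2.T + A2 @ A0.T
    het_in_shared = H @ V.T  # [i, j] = het loci of i that are observed in j
    denom = het_in_shared + het_in_shared.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, (n11 - 2 * n02) / denom, np.nan)
    return pd.DataFrame(phi, index=g.samples.index, columns=g.samples.index)


# ---------------------------------------------------------------------------
# Concordance graph and identity resolution
# ---------------------------------------------------------------------------

def _pair_masks(kin: np.ndarray, brains: np.ndarray, active: np.ndarray,
                dup: float, dist: float):
    """Boolean matrices of suspicious and spurious pairs (upper+lower)."""
    n = len(brains)
    known = np.array([not is_unknown_brain(b) for b in brains])
    same = (brains[:, None] == brains[None, :]) & known[:, None] & known[None, :]
    act = active[:, None] & active[None, :]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(invalid="ignore"):
        suspicious = same & (kin < dist) & act & off
        spurious = (~same) & (kin > dup) & act & off
    return suspicious, spurious


@dataclass
class ConcordanceGraph:
    """Pairwise-kinship concordance structure over sequencing samples.

    Holds the full kinship matrix and claimed brain labels; ``graph`` is a
    networkx view containing only the flagged edges (attributes: ``kind`` in
    {suspicious, spurious} and ``kinship``), and ``flags`` the per-sample
    flag counts.
    """

    kinship: pd.DataFrame
    brain: pd.Series
    dup_threshold: float = DUPLICATE_KINSHIP
    dist_threshold: float = DISTANT_KINSHIP
    graph: nx.Graph = field(default_factory=nx.Graph)
    flags: pd.DataFrame = field(default_factory=pd.DataFrame)

    def recompute(self, active: pd.Series | None = None) -> "ConcordanceGraph":
        ids = self.kinship.index
        kin = self.kinship.to_numpy()
        brains = self.brain.loc[ids].to_numpy(dtype=object)
        act = (
            np.ones(len(ids), dtype=bool)
            if active is None
            else active.loc[ids].to_numpy(dtype=bool)
        )
        susp, spur = _pair_masks(
            kin, brains, act, self.dup_threshold, self.dist_threshold
        )
        g = nx.Graph()
        meta = getattr(self.brain, "to_dict", lambda: {})()
        for i, sid in enumerate(ids):
            if act[i]:
                g.add_node(sid, brain_id=meta.get(sid))
        iu, ju = np.triu_indices(len(ids), k=1)
        for kind, mask in (("suspicious", susp), ("spurious", spur)):
            sel = mask[iu, ju]
            for i, j in zip(iu[sel], ju[sel]):
                g.add_edge(ids[i], ids[j], kind=kind, kinship=float(kin[i, j]))
        self.graph = g
        self.flags = pd.DataFrame(
            {
                "suspicious": susp.sum(axis=1),
                "spurious": spur.sum(axis=1),
                "total": susp.sum(axis=1) + spur.sum(axis=1),
            },
            index=ids,
        )
        return self


def build_concordance_graph(
    kin: pd.DataFrame,
    claimed_brain: pd.Series,
    *,
    dup_threshold: float = DUPLICATE_KINSHIP,
    dist_threshold: float = DISTANT_KINSHIP,
) -> ConcordanceGraph:
    """Flag suspicious (same brain, phi < 0.1) and spurious (different
    brains, phi > 0.354) pairs and aggregate per-sample counts."""
    if not kin.index.equals(kin.columns):
        raise ValueError("kinship matrix must be square with matching labels")
    cg = ConcordanceGraph(kin, claimed_brain, dup_threshold, dist_threshold)
    return cg.recompute()


@dataclass
class ResolutionAction:
    sample: str
    action: str  # remap | assign | exclude
    new_brain: str | None
    iteration: int
    evidence: dict = field(default_factory=dict)


def resolve_identities(
    graph: ConcordanceGraph, *, max_rounds: int | None = None
) -> tuple[list[ResolutionAction], pd.Series]:
    """Iterative majority-voting relabeling / exclusion of flagged samples.

    In each round the sample with the most suspicious + spurious flags is
    selected (ties broken by sample id).  Its duplicate-level partners
    (kinship > dup threshold) vote with their claimed brain ids; a strict
    majority for a single brain different from the claim -- provided the
    relabel would clear all of the sample's flags -- triggers a ``remap``
    (``assign`` when the claim was unknown).  A sample whose partners
    corroborate its current claim is left alone (its flags are caused by
    others).  Anything else -- no duplicate partner, split vote, or a
    relabel that would not clear the flags -- is excluded, as is any sample
    selected for a second remap.  Flags are recomputed after every action
    because one correction can resolve several errors.

    Returns the action log and the corrected brain labels (excluded samples
    dropped).  The procedure is a pure function of (kinship matrix, labels).
    """
    ids = graph.kinship.index
    kin = graph.kinship.to_numpy()
    labels = graph.brain.loc[ids].to_numpy(dtype=object).copy()
    active = np.ones(len(ids), dtype=bool)
    dup, dist = graph.dup_threshold, graph.dist_threshold
    pos = {sid: i for i, sid in enumerate(ids)}
    remapped: set[str] = set()
    actions: list[ResolutionAction] = []
    if max_rounds is None:
        max_rounds = 2 * len(ids) + 10

    def flag_counts():
        susp, spur = _pair_masks(kin, labels, active, dup, dist)
        return susp.sum(axis=1) + spur.sum(axis=1)

    def own_flags_if(i: int, new_label, ignorable: np.ndarray) -> int:
        """Sample i's flag count after a hypothetical relabel, not counting
        pairs with samples that are themselves currently flagged -- those
        are corrected (or excluded) in later iterations, so they must not
        veto a majority-supported remap (a swap would otherwise deadlock:
        each side keeps one flag against the other)."""
        old = labels[i]
        labels[i] = new_label
        susp, spur = _pair_masks(kin, labels, active, dup, dist)
        bad = (susp[i] | spur[i]) & ~ignorable
        labels[i] = old
        return int(bad.sum())

    for rnd in range(max_rounds):
        counts = flag_counts()
        flagged = [
            (int(-counts[i]), ids[i], i)
            for i in range(len(ids))
            if active[i] and counts[i] > 0
        ]
        if not flagged:
            break
        flagged.sort()

        acted = False
        for _, sid, i in flagged:
            with np.errstate(invalid="ignore"):
                partner_idx = [
                    j
                    for j in range(len(ids))
                    if j != i and active[j] and kin[i, j] > dup
                ]
            votes: dict = {}
            for j in partner_idx:
                if not is_unknown_brain(labels[j]):
                    votes[labels[j]] = votes.get(labels[j], 0) + 1
            majority = None
            if votes:
                top = sorted(votes.items(), key=lambda kv: (-kv[1], str(kv[0])))
                if top[0][1] * 2 > len(partner_idx):
                    majority = top[0][0]

            evidence = {
                "partners": {ids[j]: float(kin[i, j]) for j in partner_idx},
                "votes": {str(k): v for k, v in votes.items()},
                "flags": int(counts[i]),
            }

            if majority is not None and majority == labels[i]:
                # corroborated by its duplicates: flags must come from others
                continue
            ignorable = (counts > 0) & active
            ignorable[i] = False
            if (
                majority is not None
                and sid not in remapped
                and own_flags_if(i, majority, ignorable) == 0
            ):
                kind = "assign" if is_unknown_brain(labels[i]) else "remap"
                labels[i] = majority
                remapped.add(sid)
                actions.append(ResolutionAction(sid, kind, majority, rnd, evidence))
            else:
                if sid in remapped and majority is not None:
                    warnings.warn(f"sample {sid} oscillated; forcing exclusion")
                active[i] = False
                actions.append(ResolutionAction(sid, "exclude", None, rnd, evidence))
            acted = True
            break

        if not acted:
            warnings.warn(
                "all flagged samples are corroborated by their duplicate "
                "partners; stopping with residual flags"
            )
            break
    else:
        warnings.warn("identity resolution hit the round cap")

    corrected = pd.Series(labels, index=ids)[pd.Series(active, index=ids)]
    return actions, corrected


def kinship_density_report(
    kin: pd.DataFrame,
    brain_before: pd.Series,
    brain_after: pd.Series,
    *,
    dup_threshold: float = DUPLICATE_KINSHIP,
    dist_threshold: float = DISTANT_KINSHIP,
) -> pd.DataFrame:
    """Fractions of discordant pairs before and after identity resolution.

    Reports, for each label set, the fraction of within-brain pairs with
    kinship below the distant threshold and the fraction of between-brain
    pairs above the duplicate threshold.  ``brain_after`` only needs to
    cover the samples that survived resolution.
    """
    def fractions(labels: pd.Series) -> tuple[float, float]:
        ids = labels.index
        k = kin.loc[ids, ids].to_numpy()
        brains = labels.to_numpy(dtype=object)
        known = np.array([not is_unknown_brain(b) for b in brains])
        same = (brains[:, None] == brains[None, :]) & known[:, None] & known[None, :]
        iu, ju = np.triu_indices(len(ids), k=1)
        same_u = same[iu, ju]
        kin_u = k[iu, ju]
        ok = ~np.isnan(kin_u)
        within = same_u & ok
        between = ~same_u & ok
        f_within = (
            float(np.mean(kin_u[within] < dist_threshold)) if within.any() else 0.0
        )
        f_between = (
            float(np.mean(kin_u[between] > dup_threshold)) if between.any() else 0.0
        )
        return f_within, f_between

    wb, bb = fractions(brain_before)
    wa, ba = fractions(brain_after)
    return pd.DataFrame(
        {
            "within_brain_low_kinship": [wb, wa],
            "between_brain_high_kinship": [bb, ba],
        },
        index=["before", "after"],
    )
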