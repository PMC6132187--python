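"""Proteomics-to-genotype sample matching via cis-pQTL genotype inference.

Proteomics carries no direct genotype, but proteins under strong cis
genetic control (cis-pQTLs) let us read genotypes off abundance: fit a
per-protein additive model ``y = beta0 + beta1 * dosage`` on cis variants,
then, for each proteomics profile, invert the model to the nearest dosage
in {0, 1, 2}.  The fraction of models where the inferred dosage matches a
genotype sample's observed dosage is a genetic-identity similarity score;
a proteomics sample is *self-aligned* when its score against its claimed
genotype partner ranks in the top 3 of its row or of its column.  Failed
samples are re-examined with a reciprocal best-match rule, relabeled when
both sides agree, models are refitted under the updated labels, and the
whole procedure iterates to convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix, GenotypeMatrix


@dataclass
class PQTLModel:
    """One protein's best cis association: y = beta0 + beta1 * dosage."""

    protein: str
    variant: str
    beta0: float
    beta1: float
    pvalue: float
    n: int
    modal_dosage: float  # cohort-modal genotype at the variant (tie-break)


@dataclass
class AlignmentScoreMatrix:
    """Similarity scores between proteomics (rows) and genotype samples
    (columns), with the model counts behind each entry."""

    scores: pd.DataFrame
    n_models: pd.DataFrame


@dataclass
class AlignmentResult:
    status: pd.Series           # self-aligned | mis-aligned | unresolved
    pairing: pd.Series          # final proteomics -> genotype assignment
    remaps: list[tuple[str, str, str]]  # (prot sample, old geno, new geno)
    n_rounds: int
    scores: AlignmentScoreMatrix
    log: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# cis-pQTL mapping
# ---------------------------------------------------------------------------

def map_cis_pqtl(
    genotypes: GenotypeMatrix,
    proteins: AbundanceMatrix,
    pairing: pd.Series,
    *,
    window_bp: int = 1_000_000,
    alpha: float = 1e-3,
    min_n: int = 3,
) -> list[PQTLModel]:
    """Fit simple linear cis associations and keep the best variant per
    protein at ``p < alpha``.

    ``pairing`` maps proteomics sample ids to genotype sample ids (the
    current claimed identities); only paired samples enter the fit.
    Proteins without coordinates or without any cis variant are skipped.
    """
    if proteins.features is None:
        raise ValueError("protein features must carry chrom/pos coordinates")
    prot_ids = [s for s in proteins.samples.index if s in pairing.index]
    geno_ids = [pairing[s] for s in prot_ids]
    missing = [g for g in geno_ids if g not in genotypes.samples.index]
    if missing:
        raise ValueError(f"pairing references unknown genotype samples: {missing[:5]}")

    D = genotypes.dosage.loc[geno_ids]  # paired samples x variants
    var_meta = genotypes.variants
    modal = D.mode(axis=0, dropna=True).iloc[0]

    models: list[PQTLModel] = []
    for prot in proteins.values.index:
        chrom = str(proteins.features.loc[prot, "chrom"])
        pos = int(proteins.features.loc[prot, "pos"])
        cis = var_meta.index[
            (var_meta["chrom"].astype(str) == chrom)
            & ((var_meta["pos"] - pos).abs() <= window_bp)
        ]
        if len(cis) == 0:
            continue
        y = proteins.values.loc[prot, prot_ids].to_numpy(dtype=float)
        X = D[cis].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        best = None
        yv = y[ok]
        Xv = X[ok]
        valid = ~np.isnan(Xv)
        n_each = valid.sum(axis=0)
        for j, v in enumerate(cis):
            n = int(n_each[j])
            if n < min_n:
                continue
            x = Xv[valid[:, j], j]
            yy = yv[valid[:, j]]
            sx = x.std()
            if sx == 0:
                continue
            r = float(np.corrcoef(x, yy)[0, 1])
            if np.isnan(r):
                continue
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1 - r * r))
                p = 2.0 * float(stats.t.sf(abs(t), n - 2))
            b1 = r * yy.std() / sx
            b0 = float(yy.mean() - b1 * x.mean())
            if b1 == 0:
                continue
            cand = PQTLModel(prot, str(v), b0, float(b1), p, n, float(modal[v]))
            if best is None or cand.pvalue < best.pvalue:
                best = cand
        if best is not None and best.pvalue < alpha:
            models.append(best)
    return models


# ---------------------------------------------------------------------------
# Genotype inference and similarity
# ---------------------------------------------------------------------------

def infer_genotypes(profile: pd.Series, models: list[PQTLModel]) -> pd.Series:
    """Invert fitted cis models to dosages for one proteomics profile.

    For each model the inferred dosage is the g in {0, 1, 2} minimizing
    |y - (beta0 + beta1 * g)|; exact ties break toward the cohort-modal
    genotype.  Models whose protein is missing in the profile (or with
    beta1 = 0, which carries no information) yield NaN.
    """
    out = pd.Series(np.nan, index=[m.variant for m in models], dtype=float)
    for m in models:
        if m.beta1 == 0:
            continue
        y = profile.get(m.protein, np.nan)
        if pd.isna(y):
            continue
        dists = np.abs(y - (m.beta0 + m.beta1 * np.array([0.0, 1.0, 2.0])))
        best = dists.min()
        ties = np.flatnonzero(np.isclose(dists, best))
        if len(ties) > 1 and not np.isnan(m.modal_dosage):
            g = (
                m.modal_dosage
                if m.modal_dosage in ties.astype(float)
                else float(ties[0])
            )
        else:
            g = float(ties[0])
        out[m.variant] = g
    return out


def similarity_matrix(
    proteomics: AbundanceMatrix,
    genotypes: GenotypeMatrix,
    models: list[PQTLModel],
    *,
    min_models_per_pair: int = 10,
) -> AlignmentScoreMatrix:
    """Genotype-concordance similarity between every proteomics and
    genotype sample.

    S_ij is the fraction of models where the dosage inferred from
    proteomics sample i equals genotype sample j's observed dosage, over
    models where both sides are defined; pairs with fewer than
    ``min_models_per_pair`` comparable models are undefined (NaN).
    """
    if len(models) < 20:
        warnings.warn(f"only {len(models)} usable cis-pQTL models; scores are noisy")
    variants = [m.variant for m in models]
    inferred = np.vstack(
        [
            infer_genotypes(proteomics.values[s], models).to_numpy()
            for s in proteomics.samples.index
        ]
    )  # prot samples x models
    observed = genotypes.dosage[variants].to_numpy(dtype=float)  # geno x models

    vi = ~np.isnan(inferred)
    vo = ~np.isnan(observed)
    matches = np.zeros((inferred.shape[0], observed.shape[0]))
    for g in (0.0, 1.0, 2.0):
        matches += (np.where(vi, inferred == g, False).astype(float)) @ (
            np.where(vo, observed == g, False).astype(float).T
        )
    counts = vi.astype(float) @ vo.astype(float).T
    with np.errstate(invalid="ignore"):
        S = np.where(counts >= min_models_per_pair, matches / counts, np.nan)
    idx = proteomics.samples.index
    cols = genotypes.samples.index
    return AlignmentScoreMatrix(
        scores=pd.DataFrame(S, index=idx, columns=cols),
        n_models=pd.DataFrame(counts, index=idx, columns=cols),
    )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _rank_in(values: pd.Series, target: str) -> int:
    """Descending rank of ``values[target]``; NaNs last, ties by label."""
    v = values.loc[target]
    if pd.isna(v):
        return len(values)
    order = sorted(
        values.index, key=lambda k: (-(values[k] if pd.notna(values[k]) else -np.inf), str(k))
    )
    return order.index(target) + 1


def classify_alignment(
    S: AlignmentScoreMatrix, pairing: pd.Series, *, top_k: int = 3
) -> pd.DataFrame:
    """Single-round top-k self-alignment classification.

    A proteomics sample is self-aligned when the score against its claimed
    genotype partner ranks in the top ``top_k`` of its row (across genotype
    profiles) *or* of its column (across proteomics profiles).
    """
    rows = []
    for p in S.scores.index:
        g = pairing.get(p)
        if g is None or g not in S.scores.columns:
            rows.append({"sample": p, "row_rank": np.nan, "col_rank": np.nan,
                         "self_aligned": False})
            continue
        rr = _rank_in(S.scores.loc[p], g)
        cr = _rank_in(S.scores[g], p)
        rows.append(
            {
                "sample": p,
                "row_rank": rr,
                "col_rank": cr,
                "self_aligned": (rr <= top_k) or (cr <= top_k),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def align_samples(
    proteomics: AbundanceMatrix,
    genotypes: GenotypeMatrix,
    pairing: pd.Series,
    *,
    window_bp: int = 1_000_000,
    alpha: float = 1e-3,
    top_k: int = 3,
    max_rounds: int = 20,
) -> AlignmentResult:
    """Iterative top-k self-alignment with reciprocal mismatch resolution.

    Each round: fit cis-pQTL models under the current pairing, score all
    proteomics x genotype pairs, classify self-alignment, then remap an
    unmatched proteomics profile P_i to an unmatched genotype profile G_j
    only when G_j is P_i's best genotype match *and* P_i is G_j's best
    proteomics match (reciprocal rule).  Remapping changes the labels the
    models are trained on, so models and scores are refitted and the loop
    continues until no status changes (capped at ``max_rounds``).
    """
    pairing = pairing.copy()
    remaps: list[tuple[str, str, str]] = []
    log: list[dict] = []
    prev_status = None
    S = None
    cls = None

    for rnd in range(1, max_rounds + 1):
        models = map_cis_pqtl(
            genotypes, proteomics, pairing, window_bp=window_bp, alpha=alpha
        )
        S = similarity_matrix(proteomics, genotypes, models)
        cls = classify_alignment(S, pairing, top_k=top_k)
        status = cls["self_aligned"].copy()
        log.append(
            {
                "round": rnd,
                "n_models": len(models),
                "self_aligned": int(status.sum()),
                "unmatched": int((~status).sum()),
            }
        )

        unmatched_p = [p for p in S.scores.index if not status.get(p, False)]
        matched_g = {pairing[p] for p in S.scores.index if status.get(p, False)}
        unmatched_g = [g for g in S.scores.columns if g not in matched_g]

        round_remaps = []
        taken = set()
        for p in unmatched_p:
            row = S.scores.loc[p]
            cand = [g for g in unmatched_g if g not in taken and pd.notna(row[g])]
            if not cand:
                continue
            best_g = min(cand, key=lambda g: (-row[g], str(g)))
            col = S.scores[best_g]
            best_p = min(
                col.index,
                key=lambda q: (-(col[q] if pd.notna(col[q]) else -np.inf), str(q)),
            )
            if best_p == p and pairing.get(p) != best_g:
                round_remaps.append((p, pairing.get(p), best_g))
                taken.add(best_g)

        if prev_status is not None and status.equals(prev_status) and not round_remaps:
            break
        prev_status = status
        if not round_remaps:
            break
        for p, old, new in round_remaps:
            pairing[p] = new
            remaps.append((p, old, new))
    else:
        warnings.warn(f"alignment did not converge within {max_rounds} rounds")

    final = pd.Series("unresolved", index=S.scores.index, dtype=object)
    final[cls["self_aligned"]] = "self-aligned"
    for p, _, _ in remaps:  # remapped samples were mislabeled originally
        final[p] = "mis-aligned"
    return AlignmentResult(
        status=final,
        pairing=pairing,
        remaps=remaps,
        n_rounds=len(log),
        scores=S,
        log=log,
    )
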