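"""End-to-end QC orchestration.

``run_pipeline`` chains the stages in their canonical order -- variant QC,
heterozygosity / sex / ancestry checks, pairwise kinship, iterative
identity resolution, BCMI on the proteomics matrix, and cis-pQTL alignment
of proteomics samples against the resolved genotypes -- emitting per-stage
TSV/CSV artifacts and one JSON :class:`RunReport` whose counts reconcile
(in = out + removed) at every stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bcmi, identity, io, modmatch
from .containers import AbundanceMatrix, GenotypeMatrix


@dataclass
class RunConfig:
    """Paths, thresholds and seed for one pipeline run.

    Threshold defaults are the pipeline's canonical values: 15% protein
    missing-rate cut, variant filters (missing > 0.5, MAF < 0.01,
    HWE p < 1e-3), kinship duplicate/distant thresholds 0.354 / 0.1, sex F
    cutoffs 0.8 / 0.2, cis-pQTL alpha 1e-3 in a +/- 1 Mb window.
    """

    genotypes: str | None = None
    metadata: str | None = None
    proteomics: str | None = None
    pqtl_proteins: str | None = None
    sex_markers: str | None = None
    outdir: str = "qc_out"
    rng_seed: int = 0
    missing_rate_threshold: float = 0.15
    variant_max_missing: float = 0.5
    variant_min_maf: float = 0.01
    hwe_alpha: float = 1e-3
    kinship_duplicate: float = 0.354
    kinship_distant: float = 0.1
    sex_f_male: float = 0.8
    sex_f_female: float = 0.2
    modmatch_alpha: float = 1e-3
    modmatch_window_bp: int = 1_000_000
    modmatch_top_k: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**io.load_run_config(path))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    seed: int
    config_hash: str
    stages: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def run_pipeline_objects(
    config: RunConfig,
    genotypes: GenotypeMatrix,
    proteomics: AbundanceMatrix | None = None,
    pqtl_proteins: AbundanceMatrix | None = None,
    sex_markers: AbundanceMatrix | None = None,
    outdir: Path | None = None,
) -> RunReport:
    """Run all QC stages on in-memory objects (see :func:`run_pipeline`)."""
    report = RunReport(seed=config.rng_seed, config_hash=config.config_hash())
    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- stage 1: variant QC -----------------------------------------
        g_qc, vreport = identity.variant_qc(
            genotypes,
            max_missing=config.variant_max_missing,
            min_maf=config.variant_min_maf,
            hwe_alpha=config.hwe_alpha,
        )
        report.stages["variant_qc"] = {
            "variants_in": int(genotypes.n_variants),
            "variants_out": int(g_qc.n_variants),
            "variants_removed": int(genotypes.n_variants - g_qc.n_variants),
        }
        if out is not None:
            vreport.to_csv(out / "variant_qc.tsv", sep="\t")

        # --- stage 2: sample statistics ----------------------------------
        het = identity.heterozygosity_outliers(g_qc)
        sexg = identity.impute_sex_genotype(
            g_qc,
            male_threshold=config.sex_f_male,
            female_threshold=config.sex_f_female,
        )
        sample_stats = het.join(sexg)
        sex_expr_mism = None
        if sex_markers is not None:
            calls = identity.impute_sex_expression(sex_markers)
            sample_stats = sample_stats.join(
                calls.rename("sex_call_expression"), how="left"
            )
        pcs, _ = identity.genotype_pca(g_qc)
        ancestry = identity.ancestry_check(pcs, g_qc.samples["race"])
        report.stages["sample_qc"] = {
            "samples": int(g_qc.n_samples),
            "het_outliers": int(het["flagged"].sum()),
            "sex_mismatches": int(sexg.get("mismatch", pd.Series(dtype=bool)).sum()),
            "race_mismatches": int((ancestry["status"] == "mismatch").sum()),
            "race_ambiguous": int((ancestry["status"] == "ambiguous").sum()),
        }
        if out is not None:
            sample_stats.to_csv(out / "sample_qc.tsv", sep="\t")
            ancestry.to_csv(out / "ancestry.tsv", sep="\t")
            pcs.to_csv(out / "pcs.tsv", sep="\t")

        # --- stage 3: kinship and identity resolution ---------------------
        kin = identity.kinship_matrix(g_qc)
        graph = identity.build_concordance_graph(
            kin,
            g_qc.samples["brain_id"],
            dup_threshold=config.kinship_duplicate,
            dist_threshold=config.kinship_distant,
        )
        actions, corrected = identity.resolve_identities(graph)
        density = identity.kinship_density_report(
            kin,
            g_qc.samples["brain_id"],
            corrected,
            dup_threshold=config.kinship_duplicate,
            dist_threshold=config.kinship_distant,
        )
        n_excl = sum(1 for a in actions if a.action == "exclude")
        report.stages["identity_resolution"] = {
            "samples_in": int(g_qc.n_samples),
            "suspicious_pairs": int(graph.flags["suspicious"].sum() // 2),
            "spurious_pairs": int(graph.flags["spurious"].sum() // 2),
            "remapped": sum(1 for a in actions if a.action == "remap"),
            "assigned": sum(1 for a in actions if a.action == "assign"),
            "excluded": n_excl,
            "samples_out": int(len(corrected)),
            "within_brain_low_kinship_before": float(
                density.loc["before", "within_brain_low_kinship"]
            ),
            "within_brain_low_kinship_after": float(
                density.loc["after", "within_brain_low_kinship"]
            ),
        }
        if report.stages["identity_resolution"]["samples_out"] + n_excl != int(
            g_qc.n_samples
        ):
            raise RuntimeError("identity-resolution counts do not reconcile")
        corrected_meta = g_qc.samples.loc[corrected.index].copy()
        corrected_meta["brain_id"] = corrected
        if out is not None:
            kin.to_csv(out / "kinship.tsv", sep="\t")
            pd.DataFrame(
                [
                    {
                        "sample": a.sample,
                        "action": a.action,
                        "new_brain": a.new_brain,
                        "iteration": a.iteration,
                    }
                    for a in actions
                ]
            ).to_csv(out / "resolution_actions.tsv", sep="\t", index=False)
            corrected_meta.to_csv(out / "corrected_metadata.csv")
            density.to_csv(out / "kinship_density.tsv", sep="\t")

        # --- stage 4: BCMI ------------------------------------------------
        if proteomics is not None:
            filtered = bcmi.missing_rate_filter(
                proteomics, config.missing_rate_threshold
            )
            result = bcmi.bcmi_run(filtered)
            report.stages["bcmi"] = {
                "proteins_in": int(proteomics.n_features),
                "proteins_out": int(filtered.n_features),
                "proteins_removed": int(
                    proteomics.n_features - filtered.n_features
                ),
                "gamma0": result.gamma[0],
                "gamma1": result.gamma[1],
                "n_not_converged": int((~result.params["converged"]).sum()),
            }
            if out is not None:
                result.corrected.to_csv(out / "proteomics_corrected.tsv", sep="\t")
                result.params.to_csv(out / "bcmi_params.tsv", sep="\t")

        # --- stage 5: modmatch ---------------------------------------------
        if pqtl_proteins is not None:
            pairing = _pair_by_brain(pqtl_proteins, corrected_meta)
            align = modmatch.align_samples(
                pqtl_proteins,
                g_qc.subset_samples(corrected_meta.index),
                pairing,
                window_bp=config.modmatch_window_bp,
                alpha=config.modmatch_alpha,
                top_k=config.modmatch_top_k,
            )
            counts = align.status.value_counts()
            n_paired = int(len(pairing))
            report.stages["modmatch"] = {
                "proteomics_samples": int(pqtl_proteins.n_samples),
                "paired": n_paired,
                "self_aligned": int(counts.get("self-aligned", 0)),
                "mis_aligned": int(counts.get("mis-aligned", 0)),
                "unresolved": int(counts.get("unresolved", 0)),
                "rounds": align.n_rounds,
                "self_alignment_rate": (
                    float(counts.get("self-aligned", 0)) / n_paired
                    if n_paired
                    else float("nan")
                ),
            }
            if out is not None:
                align.status.to_frame("status").to_csv(
                    out / "modmatch_status.tsv", sep="\t"
                )
                align.scores.scores.to_csv(out / "modmatch_scores.tsv", sep="\t")

        report.warnings = [str(w.message) for w in caught]
    if out is not None:
        report.to_json(out / "report.json")
    return report


def _pair_by_brain(
    proteomics: AbundanceMatrix, genotype_meta: pd.DataFrame
) -> pd.Series:
    """Pair each proteomics sample with one genotype sample of the same
    (corrected) brain; the first genotype sample per brain in index order
    is used, which keeps the pairing deterministic."""
    brain_to_geno: dict = {}
    for sid, brain in genotype_meta["brain_id"].items():
        brain_to_geno.setdefault(brain, sid)
    pairs = {}
    for psid, brain in proteomics.samples["brain_id"].items():
        g = brain_to_geno.get(brain)
        if g is not None:
            pairs[psid] = g
    if not pairs:
        raise ValueError("no proteomics sample could be paired to a genotype sample")
    return pd.Series(pairs)


def run_pipeline(config: RunConfig) -> RunReport:
    """Load the inputs named in ``config`` and run every applicable stage."""
    if config.genotypes is None:
        raise ValueError("config must name a genotype input")
    meta = io.read_metadata(config.metadata) if config.metadata else None
    genotypes = io.read_genotypes(config.genotypes, samples_meta=meta)
    proteomics = (
        io.read_abundance(config.proteomics) if config.proteomics else None
    )
    pqtl = (
        io.read_abundance(config.pqtl_proteins) if config.pqtl_proteins else None
    )
    markers = (
        io.read_abundance(config.sex_markers) if config.sex_markers else None
    )
    return run_pipeline_objects(
        config,
        genotypes,
        proteomics=proteomics,
        pqtl_proteins=pqtl,
        sex_markers=markers,
        outdir=Path(config.outdir),
    )
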