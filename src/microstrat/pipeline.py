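"""Config-driven orchestration of the full stratification analysis.

``run_pipeline`` executes: load/simulate -> relative abundance & taxonomy
aggregation -> alpha diversity -> UniFrac -> PCoA -> steady states (with
verification) -> CAGs & Wiggum over-abundance -> diet conversion -> CA & diet
groups -> HFD -> food envfit -> age-adjusted median regressions -> group
tests -> combination enrichment -> pairing statistic -> report.  Every
intermediate is written to the output directory with a provenance header
(config hash + seed); re-running with the same config and seed reproduces
every artefact bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .associations import (
    combination_enrichment, group_tests, hfd_index, macronutrient_summary,
    median_regression,
)
from .community import (
    OtuTable, aggregate_taxonomy, alpha_diversity, check_library_size_spread,
    relative_abundance, unifrac,
)
from .ordination import fit_env_vectors, pcoa
from .stratification import (
    identify_cags, identify_diet_groups, identify_steady_states,
    pairing_statistic, wiggum_overabundance,
)
from .synthetic import SyntheticConfig, SyntheticCohort, generate_cohort

log = logging.getLogger("microstrat")

MARKER_COLUMNS = [
    "CRP", "IL6", "IL8", "IL15", "TNFa", "IP10",
    "triglycerides", "diastolic_bp", "glucose",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, loadable from a flat YAML mapping."""

    outdir: str = "microstrat_out"
    seed: int = 0
    # exactly one of the two input modes
    synthetic: dict | None = None          # kwargs for SyntheticConfig
    inputs: dict | None = None             # paths: otu_table, tree, ffq, ffq_annotations, metadata
    # analysis knobs
    prevalence_min: float = 0.20
    cag_min_abundance: float = 0.001
    cag_min_samples: int = 2
    fdr: float = 0.05
    n_states: int | str = "auto"
    n_diet_groups: int | str = "auto"
    n_cags: int | str = "auto"
    permutations: int = 999
    quantreg_bootstrap: int = 2000
    quantreg_axes: int = 3
    unifrac_variant: str = "unweighted"    # variant driving PCoA/regressions
    markers: list = field(default_factory=lambda: list(MARKER_COLUMNS))

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'synthetic' or 'inputs' must be given")
        if self.inputs is not None:
            required = {"otu_table", "tree", "ffq", "ffq_annotations", "metadata"}
            missing = required - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs missing required path(s): {sorted(missing)}")
            for key, p in self.inputs.items():
                if not Path(p).exists():
                    raise ConfigError(f"input path for {key!r} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # a location, not an analysis parameter
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    summaries: dict
    warnings: list
    artifacts: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "summaries": self.summaries,
                "warnings": self.warnings,
                "artifacts": self.artifacts,
            },
            indent=2, sort_keys=True, default=_jsonable,
        )

    def to_markdown(self) -> str:
        lines = ["# microstrat run report", "",
                 f"- config hash: `{self.config_hash}`",
                 f"- seed: {self.seed}", ""]
        for stage, summary in self.summaries.items():
            lines.append(f"## {stage}")
            for k, v in summary.items():
                lines.append(f"- {k}: {_fmt(v)}")
            lines.append("")
        if self.warnings:
            lines.append("## warnings")
            lines += [f"- {w}" for w in self.warnings]
        return "\n".join(lines) + "\n"


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.6g}"
    return v


def write_cohort(cohort: SyntheticCohort, outdir, provenance: str | None = None) -> dict:
    """Write a synthetic cohort to one directory and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": "otu_table.tsv",
        "tree": "tree.nwk",
        "ffq": "ffq.csv",
        "ffq_annotations": "ffq_annotations.csv",
        "metadata": "metadata.csv",
        "truth": "truth.csv",
    }
    mio.write_otu_tsv(cohort.otu_table, outdir / paths["otu_table"], provenance)
    mio.write_tree(cohort.tree, outdir / paths["tree"])
    mio.write_ffq(cohort.ffq, outdir / paths["ffq"], outdir / paths["ffq_annotations"], provenance)
    mio.write_metadata_csv(cohort.metadata, outdir / paths["metadata"], provenance)
    mio.write_metadata_csv(cohort.truth, outdir / paths["truth"], provenance)
    manifest = {"seed": cohort.config.seed, "paths": paths,
                "n_samples": len(cohort.truth)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_inputs(config: PipelineConfig):
    """Load (otu_table, tree, ffq, metadata, truth?) per the config mode."""
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        syn.setdefault("seed", config.seed)
        if "state_diversity_gradient" in syn:
            syn["state_diversity_gradient"] = tuple(syn["state_diversity_gradient"])
        cohort = generate_cohort(SyntheticConfig(**syn))
        return cohort.otu_table, cohort.tree, cohort.ffq, cohort.metadata, cohort
    paths = config.inputs
    table = (
        mio.read_biom_json(paths["otu_table"])
        if str(paths["otu_table"]).endswith(".json")
        else mio.read_otu_tsv(paths["otu_table"])
    )
    tree = mio.read_tree(paths["tree"])
    ffq = mio.read_ffq(paths["ffq"], paths["ffq_annotations"])
    metadata = mio.read_metadata_csv(paths["metadata"])
    return table, tree, ffq, metadata, None


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; returns the report (also written to disk)."""
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = f"microstrat config={config.config_hash()} seed={config.seed}"
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2 ** 31)
    summaries: dict = {}
    warnings_log: list = []
    artifacts: list = []

    def note_artifact(name):
        artifacts.append(name)

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t_start)

    stage("load")
    table, tree, ffq, metadata, cohort = load_inputs(config)
    if cohort is not None:
        write_cohort(cohort, outdir / "cohort", prov)
        note_artifact("cohort/")
    n_samples, n_otus = table.counts.shape
    summaries["load"] = {"n_samples": n_samples, "n_otus": n_otus,
                         "n_foods": ffq.consumption.shape[1]}

    stage("diversity")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        check_library_size_spread(table)
    warnings_log.extend(str(w.message) for w in caught)
    alpha = pd.DataFrame({
        "shannon": alpha_diversity(table, "shannon"),
        "observed": alpha_diversity(table, "observed"),
        "faith_pd": alpha_diversity(table, "faith_pd", tree=tree),
    })
    mio.write_metadata_csv(alpha, outdir / "alpha_diversity.csv", prov)
    note_artifact("alpha_diversity.csv")
    summaries["alpha_diversity"] = {
        "shannon_range": [float(alpha["shannon"].min()), float(alpha["shannon"].max())],
        "observed_range": [float(alpha["observed"].min()), float(alpha["observed"].max())],
    }

    stage("unifrac")
    distances = {}
    for variant in ("unweighted", "weighted_normalized"):
        dm = unifrac(table, tree, variant)
        distances[variant] = dm
        mio.write_distance_tsv(dm, outdir / f"unifrac_{variant}.tsv", prov)
        note_artifact(f"unifrac_{variant}.tsv")

    stage("pcoa")
    main_variant = ("weighted_normalized" if config.unifrac_variant.startswith("weighted")
                    else "unweighted")
    ordinations = {}
    for variant, dm in distances.items():
        ordn = pcoa(dm)
        ordinations[variant] = ordn
        mio.write_ordination_tsv(ordn, outdir / f"pcoa_{variant}.tsv", prov)
        note_artifact(f"pcoa_{variant}.tsv")
    ordn = ordinations[main_variant]
    summaries["pcoa"] = {
        "variant": main_variant,
        "proportion_explained_1_3": [float(x) for x in ordn.proportion_explained[:3]],
    }

    stage("steady_states")
    states = identify_steady_states(
        table, prevalence_min=config.prevalence_min, k=config.n_states,
        permutations=config.permutations, seed=int(rng_seeds[0]), fdr=config.fdr,
    )
    mio.write_labels_csv(states.labels, outdir / "steady_states.csv", prov)
    states.verification.to_csv(outdir / "steady_state_verification.csv", index=False)
    note_artifact("steady_states.csv")
    note_artifact("steady_state_verification.csv")
    summaries["steady_states"] = {
        "k": states.k,
        "cluster_sizes": states.labels.value_counts().sort_index().to_dict(),
        "n_otus_retained": states.n_otus_retained,
        "permanova_pseudo_F": states.permanova_result.statistic,
        "permanova_p": states.permanova_result.p_value,
    }

    stage("cags")
    cags = identify_cags(
        table, min_abundance=config.cag_min_abundance,
        min_samples=config.cag_min_samples, fdr=config.fdr, k=config.n_cags,
    )
    mio.write_edge_list(cags.edges, outdir / "cag_edges.tsv", prov)
    cags.labels.to_frame().assign(
        dominant=lambda d: d["cag"].map(cags.dominant)
    ).to_csv(outdir / "cag_labels.csv", index_label="genus")
    note_artifact("cag_edges.tsv")
    note_artifact("cag_labels.csv")
    wiggum = wiggum_overabundance(table, states, cags)
    long = wiggum.ratios.stack().rename("ratio").reset_index()
    long.columns = ["cluster", "genus", "ratio"]
    long["cag"] = long["genus"].map(wiggum.cags)
    long.to_csv(outdir / "wiggum.csv", index=False, float_format=mio.FLOAT_FMT)
    note_artifact("wiggum.csv")
    summaries["cags"] = {
        "k": cags.k,
        "dominant": cags.dominant,
        "n_significant_edges": int(len(cags.edges)),
        "n_genera": int(len(cags.labels)),
    }

    stage("diet")
    diets = identify_diet_groups(ffq.consumption, m=config.n_diet_groups)
    mio.write_labels_csv(diets.labels, outdir / "diet_groups.csv", prov)
    note_artifact("diet_groups.csv")
    hfd = hfd_index(ffq)
    macro = macronutrient_summary(ffq)
    pd.DataFrame({"hfd": hfd}).join(macro).to_csv(
        outdir / "diet_indices.csv", index_label="sample", float_format=mio.FLOAT_FMT
    )
    note_artifact("diet_indices.csv")
    hfd_by_group = hfd.groupby(diets.labels).mean()
    summaries["diet"] = {
        "m": diets.m,
        "group_sizes": diets.labels.value_counts().sort_index().to_dict(),
        "ca_axis1_variance_pct": 100.0 * diets.ca_proportion_axis1,
        "mean_hfd_by_group": {k: float(v) for k, v in hfd_by_group.items()},
    }

    stage("envfit")
    shared = [s for s in ordn.coordinates.index if s in ffq.consumption.index]
    fits = fit_env_vectors(
        ordn, ffq.consumption.loc[shared], axes=(0, 1),
        permutations=config.permutations, seed=int(rng_seeds[1]),
    )
    env_df = pd.DataFrame([
        {"variable": f.variable, "r2": f.r_squared, "p": f.p_value, "q": f.q_value,
         **{f"dir{i + 1}": d for i, d in enumerate(f.direction)}}
        for f in fits
    ])
    env_df.to_csv(outdir / "envfit_foods.csv", index=False, float_format=mio.FLOAT_FMT)
    note_artifact("envfit_foods.csv")
    sig = env_df[env_df["q"] <= 0.01]
    summaries["envfit"] = {
        "n_foods": int(len(env_df)),
        "n_significant_q01": int(len(sig)),
        "top_foods": env_df.nlargest(5, "r2")["variable"].tolist(),
    }

    stage("median_regression")
    rows = []
    axes_avail = min(config.quantreg_axes, ordn.coordinates.shape[1])
    meta = metadata.loc[ordn.coordinates.index]
    qr_rng = np.random.default_rng(int(rng_seeds[2]))
    for marker in config.markers:
        if marker not in meta.columns:
            warnings_log.append(f"marker {marker!r} missing from metadata; skipped")
            continue
        for ax in range(axes_avail):
            row = median_regression(
                meta[marker], ordn.coordinates.iloc[:, ax], meta["age"],
                n_boot=config.quantreg_bootstrap, seed=qr_rng, parameter=marker,
            )
            rows.append({"parameter": marker, "axis": ordn.coordinates.columns[ax],
                         "rc_range": row.rc_range, "rc_sd": row.rc_sd,
                         "p": row.p_value, "n": row.n})
    qr_df = pd.DataFrame(rows)
    qr_df.to_csv(outdir / "median_regression.csv", index=False, float_format=mio.FLOAT_FMT)
    note_artifact("median_regression.csv")
    sig_qr = qr_df[qr_df["p"] <= 0.05] if len(qr_df) else qr_df
    summaries["median_regression"] = {
        "n_tests": int(len(qr_df)),
        "n_significant_p05": int(len(sig_qr)),
    }

    stage("group_tests")
    genus_rel = relative_abundance(aggregate_taxonomy(table, "genus"))
    gt = group_tests(
        genus_rel.values, states.labels, prevalence_min=config.prevalence_min,
    )
    gt.to_csv(outdir / "group_tests_genus_by_state.csv", index=False, float_format=mio.FLOAT_FMT)
    note_artifact("group_tests_genus_by_state.csv")
    summaries["group_tests"] = {
        "n_features": int(len(gt)),
        "n_significant_fdr": int((gt["p_adjusted"] <= config.fdr).sum()),
    }

    stage("enrichment")
    subj = meta["subject"] if "subject" in meta.columns else pd.Series(meta.index, index=meta.index)
    pheno_col = "develops_obesity" if "develops_obesity" in meta.columns else None
    if pheno_col is None:
        warnings_log.append("no obesity phenotype column; enrichment skipped")
        enr_summary = {"skipped": True}
    else:
        # risk combination: the least-diverse half of the states (C labels are
        # ordered by descending diversity) x the lowest-HFD diet group
        n_risk = max(1, states.k // 2)
        state_set = [f"C{i}" for i in range(states.k - n_risk + 1, states.k + 1)]
        diet_set = [hfd_by_group.idxmin()]
        enr = combination_enrichment(
            states.labels, diets.labels, meta[pheno_col], state_set, diet_set,
            subject_map=subj,
        )
        enr_summary = {
            "state_set": state_set, "diet_set": diet_set,
            "table": enr.table.tolist(), "odds_ratio": enr.odds_ratio,
            "p_one_sided": enr.p_one_sided, "p_two_sided": enr.p_two_sided,
        }
        (outdir / "enrichment.json").write_text(
            json.dumps(enr_summary, indent=2, sort_keys=True, default=_jsonable))
        note_artifact("enrichment.json")
    summaries["enrichment"] = enr_summary

    stage("pairing")
    counts_per_subj = subj.value_counts()
    if (counts_per_subj == 2).all():
        pairing = pairing_statistic(
            states.distance, subj, permutations=config.permutations,
            seed=int(rng_seeds[3]),
        )
        summaries["pairing"] = {
            "mutual_nn_pairs": pairing.statistic, "p": pairing.p_value,
        }
    else:
        warnings_log.append("subjects without exactly two samples; pairing statistic skipped")
        summaries["pairing"] = {"skipped": True}

    report = RunReport(
        config_hash=config.config_hash(), seed=config.seed,
        summaries=summaries, warnings=warnings_log, artifacts=sorted(artifacts),
    )
    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.md").write_text(report.to_markdown())
    log.info("pipeline finished in %.1fs", time.time() - t_start)
    return report
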