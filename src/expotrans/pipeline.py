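"""End-to-end orchestration: simulate -> preprocess -> discover -> enrich ->
select -> qPCR -> validate -> classify, under a single YAML-serialisable
config with one master seed.

The demo configuration emulates the study design: a discovery cohort of
48 men and 50 women measured on arrays (200 genes by default), an
independent validation cohort of 75 men and 94 women measured by qPCR on the
selected candidate panels, embedded sex-specific fold changes per 5 ug/m3
taken from the packaged example panel table, and a literature disease
annotation covering the panel genes plus a pool of unaffected genes.

Every stage writes its outputs as TSV under the run directory, logs its row
counts (the funnel trail: genes in -> top 50 -> panel of 8) and contributes
to a JSON report. Re-running with the same config and seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, enrichment, io, preprocess, qpcr, regression, selection, simulate
from .errors import PipelineError

log = logging.getLogger(__name__)

_PANEL_SEXES = ("M", "F")
_EXPOSURES = ("pm10", "pm25")


@dataclass
class PipelineConfig:
    discovery: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    validation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    preprocess: preprocess.PreprocessParams = field(default_factory=preprocess.PreprocessParams)
    k: int = 50
    panel_size: int = 8
    set_size_min: int = 5
    set_size_max: int = 100
    percentile: float = 75.0
    alpha: float = 0.05
    borderline: float = 0.10
    seed: int = 0

    def to_yaml(self, path) -> None:
        def enc(obj):
            d = dataclasses.asdict(obj)
            return d

        payload = {
            "discovery": enc(self.discovery),
            "validation": enc(self.validation),
            "preprocess": enc(self.preprocess),
            "k": self.k,
            "panel_size": self.panel_size,
            "set_size_min": self.set_size_min,
            "set_size_max": self.set_size_max,
            "percentile": self.percentile,
            "alpha": self.alpha,
            "borderline": self.borderline,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)

        def sim(d):
            d = dict(d)
            d["effect_table"] = tuple(
                simulate.EffectSpec(**e) if isinstance(e, dict) else simulate.EffectSpec(*e)
                for e in d.get("effect_table", ())
            )
            d["probe_map"] = {g: tuple(p) for g, p in (d.get("probe_map") or {}).items()}
            for key in ("baseline_range", "background_range", "reference_genes"):
                if key in d and d[key] is not None:
                    d[key] = tuple(d[key])
            return simulate.SimulationConfig(**d)

        return cls(
            discovery=sim(payload["discovery"]),
            validation=sim(payload["validation"]),
            preprocess=preprocess.PreprocessParams(**payload.get("preprocess", {})),
            **{
                k: payload[k]
                for k in (
                    "k",
                    "panel_size",
                    "set_size_min",
                    "set_size_max",
                    "percentile",
                    "alpha",
                    "borderline",
                    "seed",
                )
                if k in payload
            },
        )


def validate_config(config: PipelineConfig) -> list:
    """Collect human-readable problems; an empty list means runnable."""
    problems = []
    for name, sim_cfg in (("discovery", config.discovery), ("validation", config.validation)):
        try:
            sim_cfg.validate()
        except Exception as exc:  # noqa: BLE001 - reported as data
            problems.append(f"{name}: {exc}")
    try:
        config.preprocess.validate()
    except Exception as exc:  # noqa: BLE001
        problems.append(f"preprocess: {exc}")
    if not 0 < config.percentile < 100:
        problems.append(f"percentile = {config.percentile} must lie in (0, 100)")
    if config.k < 1:
        problems.append("k must be >= 1")
    if config.panel_size < 1:
        problems.append("panel_size must be >= 1")
    if config.panel_size > config.k:
        problems.append(
            f"panel_size ({config.panel_size}) cannot exceed k ({config.k}); "
            "the panel is drawn from the top-k list"
        )
    if not 0 < config.alpha < 1:
        problems.append("alpha must lie in (0, 1)")
    if not config.alpha <= config.borderline < 1:
        problems.append("borderline band must satisfy alpha <= borderline < 1")
    return problems


# ---------------------------------------------------------------------------
# demo configuration
# ---------------------------------------------------------------------------

def default_pipeline_config(seed: int = 0, n_extra_genes: int = 184) -> PipelineConfig:
    """Demo config emulating the study design with 200 genes by default.

    Embedded discovery and validation effects come from the packaged example
    panel table (log2 of the printed fold changes per 5 ug/m3), applied to
    each gene's sex stratum in the matching cohort.
    """
    panels = selection.bundled_panels()
    panel_genes = panels["gene_id"].tolist()
    extra = [f"G{i:04d}" for i in range(1, n_extra_genes + 1)]
    universe = panel_genes + extra
    probe_map = simulate.make_probe_map(universe)

    disc_effects = tuple(
        simulate.EffectSpec(r.gene_id, r.sex, float(np.log2(r.disc_fc5)))
        for r in panels.itertuples()
    )
    val_effects = tuple(
        simulate.EffectSpec(r.gene_id, r.sex, float(np.log2(r.val_fc5)))
        for r in panels.itertuples()
    )

    discovery = simulate.SimulationConfig(
        n_men=48,
        n_women=50,
        cohort_kind="discovery",
        pm10_mean=25.9,
        pm10_sd=2.8,
        pm25_mean=17.8,
        pm25_sd=1.7,
        effect_table=disc_effects,
        probe_map=probe_map,
        seed=seed,
    )
    validation = simulate.SimulationConfig(
        n_men=75,
        n_women=94,
        cohort_kind="validation",
        pm10_mean=23.7,
        pm10_sd=2.3,
        pm25_mean=15.7,
        pm25_sd=1.2,
        effect_table=val_effects,
        seed=seed,
    )
    return PipelineConfig(discovery=discovery, validation=validation, seed=seed)


def demo_disease_annotation(universe) -> dict:
    """Bundled panel annotation extended with a deterministic pool of
    unaffected annotated genes, so the literature filter is non-trivial."""
    ann = selection.read_disease_annotation(selection.bundled_annotation_path())
    vocab = sorted(selection.DISEASE_VOCABULARY)
    extras = [g for g in universe if g not in ann]
    for i, g in enumerate(extras):
        if i % 4 == 0:  # every 4th unaffected gene gets a literature tag
            ann[g] = (vocab[i % len(vocab)],)
    return ann


def demo_gene_sets(universe, seed: int = 0) -> list:
    """Synthetic GMT content: two signal sets built around the panel genes
    plus random sets spanning the 5-100 size window (and a few outside it)."""
    panels = selection.bundled_panels()
    rng = np.random.default_rng(seed)
    pool = list(universe)
    sets = []
    for sex, name in (("M", "PM_RESPONSE_MEN"), ("F", "PM_RESPONSE_WOMEN")):
        genes = panels.loc[panels["sex"] == sex, "gene_id"].tolist()
        fillers = [g for g in pool if g not in genes][:4]
        sets.append(enrichment.GeneSet(name, "embedded signal set", tuple(genes + fillers)))
    sizes = [4, 5, 8, 12, 15, 20, 25, 30, 40, 55, 70, 85, 100, 101, 120]
    for i, size in enumerate(sizes):
        size = min(size, len(pool))
        members = tuple(rng.choice(pool, size=size, replace=False))
        sets.append(enrichment.GeneSet(f"RANDOM_SET_{i + 1:02d}", f"random size {size}", members))
    return sets


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def _stage(report, name):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            report["stages"].append(
                {"stage": name, "elapsed_s": round(time.perf_counter() - self.t0, 3)}
            )
            return False

    return _Ctx()


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage, write all intermediates under ``out_dir`` and
    return (and write) the run report."""
    problems = validate_config(config)
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(8)]

    report: dict = {"seed": config.seed, "stages": [], "counts": {}}
    config.to_yaml(out / "config.yaml")

    # -- simulate discovery -------------------------------------------------
    with _stage(report, "simulate"):
        disc_cohort = simulate.generate_cohort(config.discovery, rng_seed=seeds[0])
        raw = simulate.generate_expression(disc_cohort, config.discovery, rng_seed=seeds[1])
        annotation = simulate.annotation_frame(config.discovery.resolved_probe_map())
        universe = config.discovery.gene_ids()
        disease_ann = demo_disease_annotation(universe)
        gene_sets = demo_gene_sets(universe, seed=config.seed)
        io.write_cohort(disc_cohort, out / "cohort_discovery.tsv")
        raw.write(out / "raw_discovery.tsv")
        io.write_table(annotation, out / "probe_annotation.tsv")
        enrichment.write_gmt(gene_sets, out / "gene_sets.gmt")
        pd.DataFrame(
            {"gene_id": list(disease_ann), "tags": [";".join(t) for t in disease_ann.values()]}
        ).to_csv(out / "disease_annotation.tsv", sep="\t", index=False)
        report["counts"]["probes"] = len(raw.foreground)
        report["counts"]["discovery_n"] = len(disc_cohort)

    # -- preprocess ----------------------------------------------------------
    with _stage(report, "preprocess"):
        expr, stages = preprocess.run_preprocessing(raw, annotation, config.preprocess)
        io.write_matrix(expr, out / "expression_discovery.tsv")
        report["counts"]["preprocess"] = {s: n for s, n in stages}
        report["counts"]["genes_analyzed"] = len(expr)

    # -- discovery association scans ----------------------------------------
    discovery_results = {}
    with _stage(report, "discover"):
        for sex in _PANEL_SEXES:
            for exposure in _EXPOSURES:
                design = regression.DesignSpec(
                    exposure=exposure,
                    covariates=regression.DISCOVERY_COVARIATES,
                    stratum=sex,
                )
                res = regression.analyze(expr, disc_cohort, design)
                discovery_results[(sex, exposure)] = res
                io.write_table(res, out / f"results_{sex.lower()}_{exposure}.tsv")
        for exposure in _EXPOSURES:
            design = regression.DesignSpec(
                exposure=exposure, covariates=regression.DISCOVERY_COVARIATES, stratum="pooled"
            )
            inter = regression.interaction_scan(expr, disc_cohort, design)
            inter.rename_axis("gene").reset_index().to_csv(
                out / f"interaction_{exposure}.tsv", sep="\t", index=False
            )
        report["counts"]["significant"] = {
            f"{sex}_{exp}": int((discovery_results[(sex, exp)]["p"] < config.alpha).sum())
            for sex in _PANEL_SEXES
            for exp in _EXPOSURES
        }

    # -- enrichment ----------------------------------------------------------
    with _stage(report, "enrich"):
        for sex in _PANEL_SEXES:
            res = discovery_results[(sex, "pm10")]
            fc_table = dict(zip(res["gene"], np.log2(res["fc5"])))
            table = enrichment.enrich(
                fc_table, gene_sets, size_min=config.set_size_min, size_max=config.set_size_max
            )
            io.write_table(table, out / f"enrichment_{sex.lower()}_pm10.tsv")
            report["counts"][f"enriched_sets_{sex}"] = int((table["q"] < config.alpha).sum())

    # -- candidate selection -------------------------------------------------
    panels = {}
    with _stage(report, "select"):
        for sex in _PANEL_SEXES:
            top = selection.top_k(discovery_results[(sex, "pm10")], k=config.k)
            panel = selection.select_panel(
                top, disease_ann, panel_size=config.panel_size, sex=sex
            )
            panels[sex] = panel
            io.write_table(
                panel.table[["gene", "fc5", "p", "rank", "tags"]],
                out / f"panel_{sex.lower()}.tsv",
            )
        report["counts"]["top_k"] = config.k
        report["counts"]["panel_sizes"] = {s: len(panels[s].genes) for s in _PANEL_SEXES}

    # -- validation cohort + qPCR -------------------------------------------
    with _stage(report, "qpcr"):
        val_cohort = simulate.generate_cohort(config.validation, rng_seed=seeds[2])
        assay_genes = sorted(set(panels["M"].genes) | set(panels["F"].genes))
        cq = simulate.generate_cq(
            val_cohort, config.validation, rng_seed=seeds[3], assays=assay_genes
        )
        io.write_cohort(val_cohort, out / "cohort_validation.tsv")
        io.write_cq(cq, out / "cq_validation.tsv")
        processed = qpcr.process_cq_table(cq, config.validation.reference_genes)
        io.write_table(processed, out / "nrq_validation.tsv")
        nrq = qpcr.nrq_matrix(processed, assays=assay_genes)
        io.write_matrix(nrq, out / "expression_validation.tsv")
        report["counts"]["validation_n"] = len(val_cohort)
        report["counts"]["qpcr_wells"] = len(cq)
        report["counts"]["qpcr_retained"] = len(processed)

    # -- validation regression + concordance ---------------------------------
    validation_results = {}
    with _stage(report, "validate"):
        for sex in _PANEL_SEXES:
            genes = [g for g in panels[sex].genes if g in nrq.index]
            for exposure in _EXPOSURES:
                design = regression.DesignSpec(
                    exposure=exposure,
                    covariates=regression.VALIDATION_COVARIATES,
                    stratum=sex,
                )
                res = regression.analyze(nrq.loc[genes], val_cohort, design)
                validation_results[(sex, exposure)] = res
                io.write_table(res, out / f"validation_{sex.lower()}_{exposure}.tsv")
        verdict_counts = {}
        for sex in _PANEL_SEXES:
            table = selection.concordance_table(
                discovery_results[(sex, "pm10")],
                validation_results[(sex, "pm10")],
                alpha=config.alpha,
                borderline=config.borderline,
            )
            io.write_table(table, out / f"concordance_{sex.lower()}_pm10.tsv")
            verdict_counts[sex] = table["status"].value_counts().to_dict()
        report["counts"]["concordance"] = verdict_counts

    # -- ROC classification ---------------------------------------------------
    with _stage(report, "classify"):
        roc_summary = []
        val_idx = val_cohort.set_index("sample_id")
        for sex in _PANEL_SEXES:
            genes = [g for g in panels[sex].genes if g in nrq.index]
            sub = val_idx[val_idx["sex"] == sex]
            X = nrq.loc[genes, [s for s in sub.index if s in nrq.columns]].T.dropna()
            sub = sub.loc[X.index]
            for exposure in _EXPOSURES:
                labels = classify.dichotomize(sub[exposure], percentile=config.percentile)
                model = classify.fit_panel_score(X, labels)
                scores = model.score(X)
                roc = classify.roc_auc(scores, labels)
                ci, p = classify.auc_inference(scores, labels, rng_seed=seeds[4])
                cv = classify.cross_validated_auc(X, labels, rng_seed=seeds[5])
                io.write_table(
                    pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}),
                    out / f"roc_{sex.lower()}_{exposure}.tsv",
                )
                roc_summary.append(
                    {
                        "sex": sex,
                        "exposure": exposure,
                        "cutoff_ugm3": round(labels.cutoff, 4),
                        "n_high": labels.n_high,
                        "n_low": labels.n_low,
                        "auc_insample": round(roc.auc, 4),
                        "auc_cv5": round(cv, 4),
                        "ci_low": round(ci[0], 4),
                        "ci_high": round(ci[1], 4),
                        "p_vs_chance": float(f"{p:.3g}"),
                    }
                )
        io.write_table(pd.DataFrame(roc_summary), out / "roc_summary.tsv")
        report["roc"] = roc_summary

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "report.txt", "w") as fh:
        fh.write(render_report(report))
    return report


def render_report(report: dict) -> str:
    """Human-readable run summary."""
    lines = [f"run seed: {report['seed']}", ""]
    counts = report["counts"]
    lines.append("funnel:")
    pp = counts.get("preprocess", {})
    for stage, n in pp.items():
        lines.append(f"  {stage:<24s} {n:>6d} rows")
    lines.append(f"  top-k per sex            {counts.get('top_k', '?'):>6}")
    for sex, size in counts.get("panel_sizes", {}).items():
        lines.append(f"  panel ({sex})                {size:>6d} genes")
    lines.append("")
    lines.append("concordance (PM10):")
    for sex, verdicts in counts.get("concordance", {}).items():
        lines.append(f"  {sex}: " + ", ".join(f"{k}={v}" for k, v in sorted(verdicts.items())))
    lines.append("")
    lines.append("ROC panels:")
    for row in report.get("roc", []):
        lines.append(
            f"  {row['sex']} {row['exposure']}: AUC={row['auc_insample']:.3f} "
            f"(95% CI {row['ci_low']:.3f}-{row['ci_high']:.3f}, p={row['p_vs_chance']:.2g}; "
            f"5-fold CV {row['auc_cv5']:.3f}; cutoff {row['cutoff_ugm3']} ug/m3, "
            f"{row['n_high']} high / {row['n_low']} low)"
        )
    lines.append("")
    lines.append("stage timings:")
    for st in report["stages"]:
        lines.append(f"  {st['stage']:<12s} {st['elapsed_s']:.2f} s")
    return "\n".join(lines) + "\n"
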