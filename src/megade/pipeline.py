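"""End-to-end orchestration: simulate/load -> effects -> pool -> screen ->
forest/regress -> overlap/enrich, as one reproducible, audited run.

A run is driven by a :class:`RunConfig` (usually loaded from YAML), writes
every stage's table into the output directory and records a manifest with
the config hash, package versions, the seed and per-stage row counts.  The
log keeps one line per stage with genes-in/genes-out style counts so that
analogous bookkeeping (how many genes entered the screen, how many were
excluded and why) is auditable after the fact.

Given the same config and seed a run is deterministic: result TSVs are
byte-identical across repeats.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .effects import collect_effects, normalize_log2
from .enrichment import enrich_sets, fisher_overlap
from .io import (
    StudyMeta,
    read_expression_matrix,
    read_gene_list,
    read_gene_sets,
    read_registry,
    write_results,
)
from .moderators import fit_moderators
from .pooling import ScreenCriteria, forest_table, pool_effects, screen_genes
from .simulate import SimulationConfig, generate_studies

__all__ = ["RunConfig", "run_pipeline", "exclude_shared"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs, validated up front."""

    outdir: str = "megade_run"
    seed: int = 0
    simulate: dict[str, Any] | None = None
    registry: str | None = None
    matrices: list[dict[str, str]] | None = None
    already_log: bool = True
    normalize: str = "median"
    q_alpha: float = 0.05
    tau2_method: str = "DL"
    criteria: dict[str, float] = field(default_factory=dict)
    forest_gene: str | None = None
    moderator_terms: list[str] = field(default_factory=lambda: ["size", "region", "year"])
    list_a: str | None = None
    list_b: str | None = None
    gmt: str | None = None
    background: int = 20000

    def __post_init__(self) -> None:
        self.screen_criteria = ScreenCriteria(**self.criteria)  # validates thresholds
        if not (0 < self.q_alpha < 1):
            raise ValueError("q_alpha must be in (0, 1)")
        if self.simulate is None and not (self.registry and self.matrices):
            raise ValueError(
                "config must either give a simulate block or registry + matrices"
            )
        for key in ("registry", "list_a", "list_b", "gmt"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise ValueError(f"{key} path does not exist: {path}")
        for entry in self.matrices or []:
            for k in ("matrix", "samples"):
                if not Path(entry[k]).exists():
                    raise ValueError(f"matrix path does not exist: {entry[k]}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def canonical(self) -> str:
        payload = {
            k: v for k, v in self.__dict__.items() if k != "screen_criteria"
        }
        return json.dumps(payload, sort_keys=True, default=str)


def exclude_shared(candidate_list, other_list) -> list[str]:
    """Order-preserving set difference of two gene lists; counts logged."""
    if not candidate_list or not other_list:
        raise ValueError("both gene lists must be non-empty")
    other = set(other_list)
    kept = [g for g in candidate_list if g not in other]
    n_removed = len(candidate_list) - len(kept)
    assert len(candidate_list) - n_removed == len(kept)
    return kept


def _load_studies(config: RunConfig):
    metas = {m.study_id: m for m in read_registry(config.registry)}
    studies = []
    for entry in config.matrices:
        sid = entry["study_id"]
        if sid not in metas:
            raise PipelineError(f"input: study {sid!r} missing from registry")
        studies.append(
            read_expression_matrix(entry["matrix"], entry["samples"], metas[sid])
        )
    return studies


def run_pipeline(config: RunConfig) -> Path:
    """Execute every configured stage; return the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    counts: dict[str, Any] = {}

    def log(stage: str, message: str) -> None:
        log_lines.append(f"[{stage}] {message}")

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- input -----------------------------------------------------------
    def stage_input():
        if config.simulate is not None:
            sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
            studies, truth = generate_studies(sim)
            log("input", f"simulated {len(studies)} studies, {sim.n_genes} genes")
            return studies, truth
        studies = _load_studies(config)
        log("input", f"loaded {len(studies)} studies from disk")
        return studies, None

    studies, truth = run_stage("input", stage_input)
    counts["n_studies"] = len(studies)

    # ---- effects ---------------------------------------------------------
    def stage_effects():
        normalized = [
            normalize_log2(s, already_log=config.already_log, method=config.normalize)
            for s in studies
        ]
        eff = collect_effects(normalized)
        write_results(eff, outdir / "effects.tsv")
        log("effects", f"{eff['gene'].nunique()} genes, {len(eff)} study-level effects")
        return eff

    effects = run_stage("effects", stage_effects)
    counts["n_effects"] = len(effects)

    # ---- pool + screen ---------------------------------------------------
    def stage_pool():
        meta = pool_effects(effects, q_alpha=config.q_alpha,
                            tau2_method=config.tau2_method)
        n_dropped = effects["gene"].nunique() - len(meta)
        log("pool", f"pooled {len(meta)} genes ({n_dropped} with k<2 skipped)")
        return meta

    meta = run_stage("pool", stage_pool)
    counts["n_pooled"] = len(meta)

    def stage_screen():
        screened = screen_genes(meta, len(studies), config.screen_criteria)
        write_results(screened, outdir / "meta.tsv")
        n_pass = int(screened["passed"].sum())
        fails = {
            "coverage": int((~screened["pass_coverage"]).sum()),
            "p": int((~screened["pass_p"]).sum()),
            "lfc": int((~screened["pass_lfc"]).sum()),
        }
        log("screen", f"{n_pass} of {len(screened)} genes pass; failures {fails}")
        return screened

    screened = run_stage("screen", stage_screen)
    counts["n_passing"] = int(screened["passed"].sum())
    passing = screened.loc[screened["passed"], "gene"].tolist()

    # ---- forest + moderators for the headline gene -----------------------
    focus = config.forest_gene or (passing[0] if passing else None)
    if focus is not None:
        def stage_forest():
            row = meta.loc[meta["gene"] == focus]
            if row.empty:
                raise ValueError(f"gene {focus!r} was not pooled")
            row = row.iloc[0]
            table = forest_table(focus, effects, model=row["model_used"],
                                 tau2=row["tau2"])
            write_results(table, outdir / "forest.tsv")
            log("forest", f"{focus}: {len(table)} studies, model {row['model_used']}")
            return table

        run_stage("forest", stage_forest)

        def stage_regress():
            registry = pd.DataFrame([s.meta.__dict__ for s in studies])
            try:
                fit = fit_moderators(effects, registry, focus,
                                     terms=tuple(config.moderator_terms))
            except ValueError as exc:
                log("regress", f"skipped: {exc}")
                return None
            write_results(fit.terms, outdir / "moderators.tsv")
            log("regress", f"{focus}: r2={fit.r2:.3f} over {fit.n_studies} studies"
                           + (f", dropped {fit.dropped}" if fit.dropped else ""))
            return fit

        run_stage("regress", stage_regress)

    # ---- overlap / enrichment -------------------------------------------
    if config.list_a and config.list_b:
        def stage_overlap():
            a = read_gene_list(config.list_a)
            b = read_gene_list(config.list_b)
            res = fisher_overlap(a, b, config.background)
            (outdir / "overlap.json").write_text(
                json.dumps(
                    {k: v for k, v in res.__dict__.items() if k != "overlap_genes"},
                    indent=1, sort_keys=True,
                )
            )
            a_specific = exclude_shared(a, b)
            Path(outdir / "list_a_specific.txt").write_text("\n".join(a_specific) + "\n")
            log("overlap",
                f"|A|={res.n_a} |B|={res.n_b} shared={res.n_overlap} "
                f"A-specific={len(a_specific)} p={res.p:.3g}")
            counts["n_overlap"] = res.n_overlap
            counts["n_a_specific"] = len(a_specific)
            return res

        run_stage("overlap", stage_overlap)

    if config.gmt and config.list_a:
        def stage_enrich():
            query = read_gene_list(config.list_a)
            collection = read_gene_sets(config.gmt)
            table = enrich_sets(query, collection, config.background)
            write_results(table, outdir / "enrichment.tsv")
            log("enrich", f"{len(table)} sets tested, "
                          f"{int((table['q'] < 0.05).sum())} at q<0.05")
            return table

        run_stage("enrich", stage_enrich)

    # ---- manifest --------------------------------------------------------
    manifest = {
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "megade": __version__,
            "python": platform.python_version(),
            "numpy": __import__("numpy").__version__,
            "scipy": __import__("scipy").__version__,
            "pandas": pd.__version__,
        },
        "counts": counts,
        "passing_genes": passing,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
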