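"""Synthetic multi-study case/control expression data with known ground truth.

The generator emulates the statistical structure of a cross-study
differential-expression mega-analysis: ``K`` independent case/control
studies measure (mostly) the same genes on a log2 scale, a fraction of genes
carry a true case-vs-control shift whose per-study realisation varies with
between-study variance tau^2, and platform differences make some genes
unmeasured in some studies (a gene can be absent from several of the K
series, as Y-chromosome probes often are).

Model, per gene g, study i, sample s::

    x_gis = baseline_g + offset_i + moderator_shift_i
            + theta_gi * 1[s is case] + N(0, within_sd)

* ``baseline_g`` — gene abundance, uniform on a configurable log2 range;
* ``offset_i`` — study/array offset, Gaussian; both are nuisance structure
  that normalization must remove;
* ``theta_gi`` — the realised case effect: 0 for null genes, otherwise
  N(mu, tau2) i.i.d. across studies;
* ``moderator_shift_i`` — optional study-level covariate effects (region,
  total sample size, year) applied to case samples, for exercising
  moderator regression;
* dropout — independent Bernoulli per (gene, study); a dropped gene is
  simply absent from that study's matrix.

A single root ``numpy`` generator seeded from ``config.seed`` governs all
draws.  Stream order: baselines, study offsets, null flags, theta matrix,
dropout mask, then per-study noise in study order — so identical
seed + config gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ExpressionStudy, StudyMeta, load_reference_registry, write_expression_study

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_studies",
    "generate_gene_lists",
    "write_studies",
]


@dataclass
class SimulationConfig:
    """Parameters of the multi-study generator.

    Per-study arm sizes default to the bundled 14-study reference registry
    (case arms 2-233), cycled if ``n_studies`` differs from 14.  ``mu`` and
    ``tau2`` give the mean and between-study variance of the true log2
    effect of non-null genes; ``within_sd`` is the residual log2-scale
    noise of a single measurement.
    """

    n_studies: int = 14
    n_genes: int = 500
    n_case: Sequence[int] | None = None
    n_control: Sequence[int] | None = None
    frac_null: float = 0.9
    mu: float = 1.0
    tau2: float = 0.15
    within_sd: float = 1.0
    dropout_prob: float = 0.2
    baseline_range: tuple[float, float] = (2.0, 12.0)
    study_offset_sd: float = 0.5
    regions: Sequence[str] | None = None
    years: Sequence[int] | None = None
    region_effects: dict[str, float] = field(default_factory=dict)
    size_slope: float = 0.0
    year_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 2:
            raise ValueError("n_studies must be >= 2 (pooling is undefined below that)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0.0 <= self.frac_null <= 1.0):
            raise ValueError("frac_null must be in [0, 1]")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be > 0")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")

        ref = load_reference_registry()
        if self.n_case is None:
            self.n_case = [ref[i % len(ref)].n_case for i in range(self.n_studies)]
        if self.n_control is None:
            self.n_control = [ref[i % len(ref)].n_control for i in range(self.n_studies)]
        self.n_case = [int(n) for n in self.n_case]
        self.n_control = [int(n) for n in self.n_control]
        if len(self.n_case) != self.n_studies or len(self.n_control) != self.n_studies:
            raise ValueError("n_case / n_control must have one entry per study")
        if min(self.n_case) < 1 or min(self.n_control) < 1:
            raise ValueError("all arm sizes must be >= 1")
        if self.regions is None:
            self.regions = [ref[i % len(ref)].country for i in range(self.n_studies)]
        if self.years is None:
            self.years = [ref[i % len(ref)].year for i in range(self.n_studies)]
        if len(self.regions) != self.n_studies or len(self.years) != self.n_studies:
            raise ValueError("regions / years must have one entry per study")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "baseline_range" in payload:
            payload["baseline_range"] = tuple(payload["baseline_range"])
        return cls(**payload)


@dataclass
class GroundTruth:
    """What the generator planted, for checking the pipeline against.

    ``theta`` is genes x studies; NaN marks (gene, study) pairs removed by
    dropout, so realised effects exist only where the gene was measured.
    """

    mu_g: pd.Series
    is_null: pd.Series
    tau2: float
    theta: pd.DataFrame

    @property
    def nonnull_genes(self) -> list[str]:
        return list(self.is_null.index[~self.is_null])


def _study_ids(n: int) -> list[str]:
    return [f"SIM{i + 1:02d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def generate_studies(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Generate the K synthetic studies and the ground truth behind them."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    study_ids = _study_ids(config.n_studies)
    K, G = config.n_studies, config.n_genes

    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, size=G)
    offsets = rng.normal(0.0, config.study_offset_sd, size=K)

    is_null = rng.random(G) < config.frac_null
    mu_g = np.where(is_null, 0.0, config.mu)

    theta = rng.normal(loc=mu_g[:, None], scale=np.sqrt(config.tau2), size=(G, K))
    theta[is_null, :] = 0.0

    # study-level moderator shifts ride on the case effect of every gene
    years = np.asarray(config.years, dtype=float)
    total_n = np.asarray(config.n_case) + np.asarray(config.n_control)
    shift = np.array(
        [config.region_effects.get(r, 0.0) for r in config.regions], dtype=float
    )
    shift += config.size_slope * total_n
    shift += config.year_slope * (years - years.mean())
    theta = theta + shift[None, :]

    measured = rng.random((G, K)) >= config.dropout_prob

    studies: list[ExpressionStudy] = []
    for i, sid in enumerate(study_ids):
        nc, nk = config.n_control[i], config.n_case[i]
        keep = measured[:, i]
        g_idx = np.nonzero(keep)[0]
        n_samp = nc + nk
        noise = rng.normal(0.0, config.within_sd, size=(len(g_idx), n_samp))
        mat = baseline[g_idx, None] + offsets[i] + noise
        mat[:, nc:] += theta[g_idx, i][:, None]  # case columns carry the effect
        samples = [f"{sid}_C{j + 1:03d}" for j in range(nc)] + [
            f"{sid}_A{j + 1:03d}" for j in range(nk)
        ]
        groups = pd.Series(
            ["control"] * nc + ["case"] * nk, index=samples, name="group"
        )
        values = pd.DataFrame(mat, index=[genes[j] for j in g_idx], columns=samples)
        meta = StudyMeta(
            study_id=sid,
            n_control=nc,
            n_case=nk,
            country=str(config.regions[i]),
            year=int(config.years[i]),
        )
        studies.append(ExpressionStudy(values=values, groups=groups, meta=meta))

    theta_df = pd.DataFrame(theta, index=genes, columns=study_ids)
    theta_df[~pd.DataFrame(measured, index=genes, columns=study_ids)] = np.nan
    truth = GroundTruth(
        mu_g=pd.Series(mu_g, index=genes, name="mu"),
        is_null=pd.Series(is_null, index=genes, name="is_null"),
        tau2=config.tau2,
        theta=theta_df,
    )
    return studies, truth


def generate_gene_lists(
    background_size: int,
    size_a: int,
    size_b: int,
    overlap: int,
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Two gene lists with an exact overlap, drawn from a synthetic background.

    Returns ``(list_a, list_b, background)`` where ``|A| = size_a``,
    ``|B| = size_b`` and ``|A & B| = overlap`` by construction.
    """
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed either list size")
    if size_a + size_b - overlap > background_size:
        raise ValueError("lists do not fit in the background universe")
    if min(size_a, size_b) < 1 or background_size < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    background = [f"BG{i + 1:06d}" for i in range(background_size)]
    picked = rng.choice(background_size, size=size_a + size_b - overlap, replace=False)
    shared = [background[i] for i in picked[:overlap]]
    only_a = [background[i] for i in picked[overlap:size_a]]
    only_b = [background[i] for i in picked[size_a:]]
    return shared + only_a, shared + only_b, background


def write_studies(
    studies: Sequence[ExpressionStudy],
    truth: GroundTruth,
    config: SimulationConfig,
    outdir: str | Path,
) -> Path:
    """Write matrices, sample sheets, registry, ground truth and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry_rows = []
    for st in studies:
        sid = st.meta.study_id
        write_expression_study(
            st, outdir / f"{sid}_matrix.tsv", outdir / f"{sid}_samples.csv"
        )
        registry_rows.append(
            {
                "study_id": sid,
                "n_control": st.meta.n_control,
                "n_case": st.meta.n_case,
                "country": st.meta.country,
                "year": st.meta.year,
            }
        )
    pd.DataFrame(registry_rows).to_csv(outdir / "registry.csv", index=False)
    truth_tbl = truth.theta.copy()
    truth_tbl.insert(0, "mu", truth.mu_g)
    truth_tbl.insert(1, "is_null", truth.is_null.astype(int))
    truth_tbl.index.name = "gene"
    truth_tbl.to_csv(outdir / "ground_truth.tsv", sep="\t", float_format="%.10g")
    config.to_yaml(outdir / "sim_config.yaml")
    return outdir
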