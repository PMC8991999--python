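"""End-to-end orchestration: generate, resample, tabulate, report.

A :class:`RunConfig` ties together the population spec, the univariate
resampling grid, the alpha grid and the multivariate config under one
master seed.  :func:`run_pipeline` executes the stages in method order —
population, split, univariate resampling, error calculus, analytic
cross-check, multivariate learning curves — and writes TSV summary
tables, an HDF5 container for the large resampling arrays, and a JSON
manifest with every seed, so a rerun with the same config reproduces the
outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analytic import power_fisher
from .errors import (DEFAULT_ALPHAS, error_rates, ground_truth_masks,
                     inflation_rates, replication_rate)
from .multivariate import MultivariateConfig, multivariate_learning_curve
from .synthpop import (PopulationSpec, generate_population,
                       split_discovery_replication)
from .univariate import ResamplingGrid, default_grid, resample_bins, variability_summary

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("bwasim")

_TSV_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    population: PopulationSpec = field(default_factory=PopulationSpec)
    alphas: tuple = DEFAULT_ALPHAS
    grid: Optional[ResamplingGrid] = None  # None: canonical bins for the population
    multivariate: Optional[MultivariateConfig] = None
    preset: str = "desk"  # "desk" | "full"
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self):
        if self.preset not in ("desk", "full"):
            raise ValueError("preset must be 'desk' or 'full'")

    # Resolved stage configs -------------------------------------------------

    def resolved_grid(self) -> ResamplingGrid:
        if self.grid is not None:
            return self.grid
        B = 200 if self.preset == "desk" else 1000
        return default_grid(self.population.n_participants, B=B, seed=self.seed)

    def resolved_multivariate(self, discovery_size: int) -> MultivariateConfig:
        if self.multivariate is not None:
            return self.multivariate
        bins = tuple(b for b in (25, 60, 145, 350, 825) if b <= discovery_size)
        if self.preset == "full":
            from .multivariate import MULTIVARIATE_BINS
            bins = tuple(b for b in MULTIVARIATE_BINS if b < discovery_size)
            bins += (discovery_size,)
            return MultivariateConfig(bins=bins, seed=self.seed)
        return MultivariateConfig(bins=bins, n_bootstrap=20, n_permutations=200,
                                  seed=self.seed)

    # Serialization ----------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "population": self.population.to_dict(),
            "alphas": list(self.alphas),
            "preset": self.preset,
            "seed": self.seed,
            "make_plots": self.make_plots,
        }
        if self.grid is not None:
            d["grid"] = dataclasses.asdict(self.grid)
            d["grid"]["bins"] = list(self.grid.bins)
        if self.multivariate is not None:
            d["multivariate"] = dataclasses.asdict(self.multivariate)
            d["multivariate"]["bins"] = list(self.multivariate.bins)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        kw["population"] = PopulationSpec.from_dict(d.get("population", {}))
        if "alphas" in kw:
            kw["alphas"] = tuple(kw["alphas"])
        if kw.get("grid") is not None:
            g = dict(kw["grid"])
            g["bins"] = tuple(g["bins"])
            kw["grid"] = ResamplingGrid(**g)
        if kw.get("multivariate") is not None:
            m = dict(kw["multivariate"])
            m["bins"] = tuple(m["bins"])
            kw["multivariate"] = MultivariateConfig(**m)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_TSV_FMT)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all stages and write results under ``outdir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "bwasim_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "outputs": [],
        "stages": {},
    }

    # Stage 1: population + split.
    log.info("stage synthpop: generating population")
    spec = dataclasses.replace(config.population, seed=config.seed)
    pop = generate_population(spec)
    split = split_discovery_replication(pop, seed=config.seed)
    manifest["stages"]["synthpop"] = {
        "n_participants": pop.n_participants,
        "n_features": pop.n_features,
        "discovery_size": int(split.discovery_ids.size),
        "replication_size": int(split.replication_ids.size),
    }

    y = pop.phenotype("cognition_composite")

    # Stage 2: univariate resampling.
    grid = config.resolved_grid()
    log.info("stage univariate: %d bins x %d iterations", len(grid.bins), grid.B)
    res = resample_bins(pop.features, y, grid, dtype=np.float32)
    strongest = int(np.nanargmax(np.abs(res.full_sample_r)))
    var_tab = variability_summary(res, strongest)
    var_tab.insert(0, "feature", strongest)
    _write_tsv(var_tab, outdir / "sampling_variability.tsv")
    with h5py.File(outdir / "resampling.h5", "w") as f:
        f.create_dataset("estimates", data=res.estimates, compression="gzip")
        f.create_dataset("pvalues", data=res.pvalues, compression="gzip")
        f.create_dataset("full_sample_r", data=res.full_sample_r)
        f.create_dataset("full_sample_p", data=res.full_sample_p)
        f.attrs["bins"] = grid.bins
    manifest["stages"]["univariate"] = {
        "bins": list(grid.bins), "B": grid.B,
        "strongest_feature": strongest,
        "max_abs_r": float(np.nanmax(np.abs(res.full_sample_r))),
        "median_abs_r": float(np.nanmedian(np.abs(res.full_sample_r))),
    }

    # Stage 3: error calculus.
    log.info("stage errors: FN/FP/sign/inflation/replication")
    masks = ground_truth_masks(res.full_sample_p, config.alphas)
    err = error_rates(res, masks, config.alphas)
    infl = inflation_rates(res, masks, config.alphas)
    table = pd.concat([err.table, infl.table], ignore_index=True)
    _write_tsv(table, outdir / "error_rates.tsv")
    rep_grid = ResamplingGrid(
        bins=tuple(b for b in grid.bins if b <= split.discovery_ids.size),
        B=grid.B, seed=grid.seed,
    )
    rep = replication_rate(pop.features, y, split, rep_grid, config.alphas)
    _write_tsv(rep, outdir / "replication_rates.tsv")
    manifest["stages"]["errors"] = {"alphas": list(config.alphas)}

    # Stage 4: analytic cross-check — resampled power vs Fisher z power at
    # the realized full-sample effect, for the strongest feature.
    log.info("stage analytic: power cross-check")
    r_star = float(res.full_sample_r[strongest])
    rows = []
    for alpha in config.alphas:
        for bi, nb in enumerate(grid.bins):
            pv = res.pvalues[strongest, bi]
            ok = ~np.isnan(pv)
            emp = float((pv[ok] < alpha).mean()) if ok.any() else np.nan
            rows.append(dict(bin=nb, alpha=alpha, empirical_power=emp,
                             analytic_power=power_fisher(abs(r_star), nb, alpha)))
    _write_tsv(pd.DataFrame(rows), outdir / "analytic_crosscheck.tsv")
    manifest["stages"]["analytic"] = {"feature": strongest, "full_sample_r": r_star}

    # Stage 5: multivariate learning curves (SVR; CCA on the battery).
    mv_cfg = config.resolved_multivariate(int(split.discovery_ids.size))
    log.info("stage multivariate: SVR + CCA, %d bins x %d bootstraps",
             len(mv_cfg.bins), mv_cfg.n_bootstrap)
    svr_res = multivariate_learning_curve(
        pop.features, y, split, dataclasses.replace(mv_cfg, method="svr"))
    _write_tsv(svr_res.summary(), outdir / "multivariate_svr.tsv")
    cca_res = multivariate_learning_curve(
        pop.features, pop.battery("cognition"), split,
        dataclasses.replace(mv_cfg, method="cca"))
    _write_tsv(cca_res.summary(), outdir / "multivariate_cca.tsv")
    manifest["stages"]["multivariate"] = {
        "bins": list(mv_cfg.bins), "n_bootstrap": mv_cfg.n_bootstrap,
    }

    # Stage 6: the three summary curves vs sample size — sampling-variability
    # width, cumulative statistical error at alpha = 0.05, and out-of-sample
    # multivariate association normalized by the full-bin in-sample mean.
    log.info("stage report: summary curves")
    alpha0 = config.alphas[0]
    svr_sum = svr_res.summary()
    norm = svr_sum.mean_in_r.iloc[-1]
    cum_rows = []
    for bi, nb in enumerate(grid.bins):
        errs = sum(
            0.0 if np.isnan(v) else v
            for v in (
                err.rate("FN", nb, alpha0),
                err.rate("FP", nb, alpha0),
                err.rate("sign", nb, alpha0),
                infl.rate("inflation_100", nb, alpha0),
            )
        )
        row = dict(
            bin=nb,
            variability_halfwidth99=float(var_tab.loc[bi, "halfwidth99"]),
            cumulative_error=errs,
        )
        mv_match = svr_sum[svr_sum.bin <= nb]
        row["normalized_out_of_sample"] = (
            float(mv_match.mean_out_r.iloc[-1] / norm) if len(mv_match) and norm else np.nan
        )
        cum_rows.append(row)
    summary = pd.DataFrame(cum_rows)
    _write_tsv(summary, outdir / "summary_curves.tsv")

    if config.make_plots:
        _plot_summary(summary, outdir / "summary_curves.png")
        manifest["outputs"].append("summary_curves.png")

    manifest["outputs"] = sorted(
        manifest["outputs"] + [p.name for p in outdir.glob("*.tsv")] + ["resampling.h5"]
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _plot_summary(summary: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(summary.bin, summary.variability_halfwidth99, label="99% half-width")
    ax.plot(summary.bin, summary.cumulative_error, label="cumulative error")
    ax.plot(summary.bin, summary.normalized_out_of_sample,
            label="normalized out-of-sample r")
    ax.set_xscale("log")
    ax.set_xlabel("sample size")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
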