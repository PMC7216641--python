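"""Posterior summarization, convergence diagnostics and forest plots.

All fits in this package report the posterior mean with an equal-tailed
95% credible interval, computed from the retained draws by linear
interpolation of the (2.5, 97.5) percentiles — the numpy default — so a
summary is bit-reproducible given the draws.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import arviz as az
import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["PosteriorSummary", "SamplerSettings", "summarize", "chain_diagnostics", "forest_plot"]

#: R-hat above which a fit is flagged; stricter than the classical 1.1
#: because these models are small and reruns are cheap.
RHAT_WARN = 1.01


@dataclasses.dataclass(frozen=True)
class SamplerSettings:
    """MCMC run configuration.

    ``iterations_per_chain`` counts total iterations including warmup;
    the default 4 chains × 2000 iterations with half discarded as warmup
    retains 4000 draws.
    """

    chains: int = 4
    iterations_per_chain: int = 2000
    warmup: int | None = None  # default: half of iterations_per_chain
    seed: int = 0
    backend: str = "gibbs"

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.effective_warmup >= self.iterations_per_chain:
            raise ValueError("warmup must be < iterations_per_chain")

    @property
    def effective_warmup(self) -> int:
        return self.iterations_per_chain // 2 if self.warmup is None else self.warmup

    @property
    def draws_per_chain(self) -> int:
        return self.iterations_per_chain - self.effective_warmup


@dataclasses.dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean with equal-tailed 95% CI and sampler diagnostics."""

    mean: float
    ci_low: float
    ci_high: float
    rhat_max: float = float("nan")
    ess_min: float = float("nan")
    n_divergent: int = 0
    flag: str = "ok"

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must be <= ci_high")
        if not np.isnan(self.rhat_max) and self.rhat_max < 0.99:
            raise ValueError(f"implausible rhat {self.rhat_max}")


def summarize(draws: np.ndarray, flag: str | None = None) -> PosteriorSummary:
    """Summarize posterior draws.

    ``draws`` is either 1-D (pooled) or 2-D ``(chains, draws_per_chain)``;
    with chain structure, rank-normalized split R-hat and bulk ESS are
    attached and the convergence flag is set when R-hat exceeds 1.01.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValueError("need at least 100 draws for a stable summary")
    pooled = draws.ravel()
    mean = float(np.mean(pooled))
    lo, hi = np.percentile(pooled, [2.5, 97.5])
    rhat, ess = float("nan"), float("nan")
    if draws.ndim == 2 and draws.shape[0] >= 2:
        rhat, ess = chain_diagnostics(draws)
    if flag is None:
        flag = "warn_convergence" if (not np.isnan(rhat) and rhat > RHAT_WARN) else "ok"
    return PosteriorSummary(mean, float(lo), float(hi), rhat, ess, 0, flag)


def chain_diagnostics(draws: np.ndarray) -> tuple[float, float]:
    """Rank-normalized split R-hat and bulk ESS for (chains, draws) arrays."""
    if np.ptp(draws) == 0:
        # degenerate chains: identical constants; R-hat undefined, call it 1
        return 1.0, float(draws.size)
    ds = az.convert_to_dataset(np.ascontiguousarray(draws))
    rhat = float(az.rhat(ds)["x"].values)
    ess = float(az.ess(ds)["x"].values)
    return rhat, ess


def forest_plot(
    summaries,
    reference: list[str] | None = None,
    path: str | Path | None = None,
    xlabel: str = "reduction, % (posterior mean, 95% CI)",
) -> list[Path]:
    """Forest plot of per-analyte posterior summaries.

    ``summaries`` is a DataFrame with columns ``target, mean, ci_low,
    ci_high``; rows are laid out in ``reference`` (catalog) order, one row
    per analyte, with a zero reference line.  Writes ``<path>.png`` and
    ``<path>.svg`` deterministically (fixed hash salt, no timestamps) and
    returns the written paths.
    """
    df = summaries.copy()
    if df.empty:
        raise ValueError("no summaries to plot")
    if reference is not None:
        order = [t for t in reference if t in set(df["target"])]
        order += [t for t in df["target"] if t not in order]
        df = df.set_index("target").loc[order].reset_index()
    plt.rcParams["svg.hashsalt"] = "lipofx"
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.2))
    ypos = np.arange(len(df))[::-1]
    ax.axvline(0.0, color="0.6", lw=0.8, zorder=0)
    ax.hlines(ypos, df["ci_low"], df["ci_high"], color="C0", lw=1.5)
    ax.plot(df["mean"], ypos, "o", color="C0", ms=5)
    ax.set_yticks(ypos, df["target"])
    ax.set_xlabel(xlabel)
    fig.tight_layout()
    written: list[Path] = []
    if path is not None:
        base = Path(path).with_suffix("")
        for ext in (".png", ".svg"):
            out = base.with_suffix(ext)
            fig.savefig(out, metadata=_no_date_metadata(ext))
            written.append(out)
    plt.close(fig)
    return written


def _no_date_metadata(ext: str) -> dict:
    if ext == ".svg":
        return {"Date": None}
    return {"Software": "lipofx"}
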