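"""Monte Carlo evaluation harness for the GIED entropy estimators.

For each (n, m, scheme) cell of a study grid, PC-II samples are generated
from a known GIED, every estimator is run on every sample, and the cell is
summarized by the average estimate (AE) and mean squared error (MSE) against
the truth; when bootstrap intervals are enabled the average width (AW) and
coverage proportion (CP) against the true entropy are reported as well.

Replicate k of cell j derives its generator from (master seed, j, k), so any
cell can be reproduced independently and cells could run in parallel.
Replicates whose fit or Lindley step fails are dropped and counted, never
retried (retrying would bias the stochastic summaries).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import partial

import numpy as np
import pandas as pd

from . import model
from .bayes import LindleyError, LossSpec, PriorSpec, bayes_entropy, build_workspace, lindley
from .bootstrap import BootConfig, boot_t_ci
from .censoring import make_scheme, sample_pc2
from .entropy import EntropySpec, entropy
from .mle import FitError, fit, observed_info, plugin_entropy
from .model import GIEDParams

__all__ = ["MCConfig", "CellResult", "MCResult", "run_study", "to_table", "parse_table"]

_ESTIMATORS = ("MLE", "LBe", "EBe", "DBe")
_QUANTITIES = ("beta", "lam", "H_S", "H_R")


@dataclass(frozen=True)
class MCConfig:
    """Study design: truth, grid, replication count and estimator settings."""

    true_params: GIEDParams
    grid: tuple[tuple[int, int, str], ...]
    reps: int = 1000
    prior: PriorSpec = field(default_factory=PriorSpec)
    linex_c: float = 2.0
    alpha: float = 1.5
    include_bayes: bool = True
    boot: BootConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for n, m, kind in self.grid:
            make_scheme(kind, n, m)  # validates every cell up front


@dataclass
class CellResult:
    n: int
    m: int
    kind: str
    ae: dict  # (estimator, quantity) -> mean estimate
    mse: dict  # (estimator, quantity) -> mean squared error
    aw: dict  # (entropy kind, theta) -> average width
    cp: dict  # (entropy kind, theta) -> coverage proportion
    n_failed: int = 0
    flagged: bool = False


@dataclass
class MCResult:
    config: MCConfig
    true_entropy: dict  # 'H_S'/'H_R' -> value (computed once, shared by all cells)
    cells: list


def _cell_rng(seed: int, j: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, j, k)))


def run_study(cfg: MCConfig) -> MCResult:
    """Run the full grid; see the module docstring for the summaries."""
    shannon = EntropySpec(kind="shannon")
    renyi = EntropySpec(kind="renyi", alpha=cfg.alpha)
    truth = {
        "beta": cfg.true_params.beta,
        "lam": cfg.true_params.lam,
        "H_S": entropy(cfg.true_params, shannon).value,
        "H_R": entropy(cfg.true_params, renyi).value,
    }
    losses = {
        "LBe": LossSpec(loss="linex", c=cfg.linex_c),
        "EBe": LossSpec(loss="entropy"),
        "DBe": LossSpec(loss="degroot"),
    }
    qfn = partial(model.quantile, p=cfg.true_params)

    cells = []
    for j, (n, m, kind) in enumerate(cfg.grid):
        scheme = make_scheme(kind, n, m)
        estimates = {key: [] for key in _cross()}
        widths = {}
        covers = {}
        failed = 0
        for k in range(cfg.reps):
            rng = _cell_rng(cfg.seed, j, k)
            sample = sample_pc2(qfn, scheme, rng)
            try:
                f = fit(sample)
                hs = plugin_entropy(f, shannon)
                hr = plugin_entropy(f, renyi)
            except FitError:
                failed += 1
                continue
            rep = {
                ("MLE", "beta"): f.params.beta,
                ("MLE", "lam"): f.params.lam,
                ("MLE", "H_S"): hs,
                ("MLE", "H_R"): hr,
            }
            try:
                if cfg.include_bayes:
                    fi = observed_info(f.params, sample)
                    ws = build_workspace(f, fi, cfg.prior, sample)
                    for label, loss in losses.items():
                        rep[(label, "H_S")] = bayes_entropy(
                            sample, shannon, cfg.prior, loss, fitres=f
                        )
                        rep[(label, "H_R")] = bayes_entropy(
                            sample, renyi, cfg.prior, loss, fitres=f
                        )
                        rep[(label, "beta")] = _bayes_param(ws, losses[label], 0)
                        rep[(label, "lam")] = _bayes_param(ws, losses[label], 1)
                if cfg.boot is not None:
                    ci_s = boot_t_ci(sample, shannon, cfg.boot, rng, fitres=f)
                    ci_r = boot_t_ci(sample, renyi, cfg.boot, rng, fitres=f)
                    widths.setdefault(("H_S", cfg.boot.theta), []).append(ci_s.width)
                    covers.setdefault(("H_S", cfg.boot.theta), []).append(
                        ci_s.covers(truth["H_S"])
                    )
                    widths.setdefault(("H_R", cfg.boot.theta), []).append(ci_r.width)
                    covers.setdefault(("H_R", cfg.boot.theta), []).append(
                        ci_r.covers(truth["H_R"])
                    )
            except (FitError, LindleyError):
                failed += 1
                continue
            for key, val in rep.items():
                estimates[key].append(val)

        ae = {}
        mse = {}
        for key, vals in estimates.items():
            if vals:
                arr = np.asarray(vals)
                ae[key] = float(arr.mean())
                mse[key] = float(np.mean((arr - truth[key[1]]) ** 2))
        cells.append(
            CellResult(
                n=n,
                m=m,
                kind=kind,
                ae=ae,
                mse=mse,
                aw={k: float(np.mean(v)) for k, v in widths.items()},
                cp={k: float(np.mean(v)) for k, v in covers.items()},
                n_failed=failed,
                flagged=failed > 0.05 * cfg.reps,
            )
        )
    return MCResult(
        config=cfg,
        true_entropy={"H_S": truth["H_S"], "H_R": truth["H_R"]},
        cells=cells,
    )


def _bayes_param(ws, loss: LossSpec, index: int) -> float:
    """Bayes estimate of a single parameter under the given loss via Lindley."""
    pick = (lambda b, l: b) if index == 0 else (lambda b, l: l)
    if loss.loss == "linex":
        c = float(loss.c)
        val = lindley(lambda b, l: np.exp(-c * pick(b, l)), ws)
        if val <= 0:
            raise LindleyError("Linex parameter estimate left the admissible domain")
        return float(-np.log(val) / c)
    if loss.loss == "entropy":
        val = lindley(lambda b, l: 1.0 / pick(b, l), ws)
        return float(1.0 / val)
    return float(lindley(lambda b, l: pick(b, l) ** 2, ws) / lindley(pick, ws))


def _cross():
    return [(e, q) for e in _ESTIMATORS for q in _QUANTITIES]


def to_table(res: MCResult, quantity: str = "beta") -> pd.DataFrame:
    """One row per grid cell: n, m, CS, then AE/MSE per estimator, 4 decimals.

    Column order follows the MLE, LBe, EBe, DBe convention.
    """
    rows = []
    for cell in res.cells:
        row = {"n": cell.n, "m": cell.m, "CS": cell.kind}
        for est in _ESTIMATORS:
            if (est, quantity) in cell.ae:
                row[f"{est}_AE"] = round(cell.ae[(est, quantity)], 4)
                row[f"{est}_MSE"] = round(cell.mse[(est, quantity)], 4)
        rows.append(row)
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path_or_buf) -> None:
    df.to_csv(path_or_buf, sep="\t", index=False, float_format="%.4f")


def parse_table(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text), sep="\t")
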