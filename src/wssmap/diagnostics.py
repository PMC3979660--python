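"""MCMC convergence diagnostics: split R-hat, effective sample size.

Computations delegate to arviz (rank-normalized split R-hat and bulk ESS);
this module shapes them into a per-scalar report table and applies the
package's convergence flag (R-hat > 1.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorDraws

logger = logging.getLogger(__name__)

__all__ = ["DiagnosticsReport", "diagnostics", "rhat", "ess"]

RHAT_FLAG_THRESHOLD = 1.05


def _scalar_chains(draws: PosteriorDraws | dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if isinstance(draws, PosteriorDraws):
        return draws.scalar_table()
    return {k: np.asarray(v) for k, v in draws.items()}


def rhat(chains: np.ndarray) -> float:
    """Rank-normalized split R-hat of one scalar's (chain, draw) array."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(np.asarray(chains)))


def ess(chains: np.ndarray) -> float:
    """Bulk effective sample size of one scalar's (chain, draw) array."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(np.asarray(chains)))


@dataclass
class DiagnosticsReport:
    table: pd.DataFrame
    acceptance: pd.DataFrame | None
    flagged: list[str]

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())

    def __str__(self) -> str:
        parts = [self.table.to_string(float_format=lambda x: f"{x:.4g}")]
        if self.acceptance is not None:
            parts += ["", "acceptance rates:", self.acceptance.to_string(
                float_format=lambda x: f"{x:.3f}")]
        if self.flagged:
            parts += ["", f"FLAGGED (R-hat > {RHAT_FLAG_THRESHOLD}): "
                      + ", ".join(self.flagged)]
        return "\n".join(parts)


def diagnostics(draws: PosteriorDraws | dict[str, np.ndarray]) -> DiagnosticsReport:
    """Per-scalar R-hat and ESS table with convergence flags.

    With a single chain, R-hat is omitted (with a warning). A constant
    (zero-variance) chain has no defined ESS and is flagged.
    """
    import arviz as az

    scalars = _scalar_chains(draws)
    any_arr = next(iter(scalars.values()))
    single_chain = any_arr.shape[0] < 2
    if single_chain:
        logger.warning("single chain: R-hat omitted")
    names = list(scalars)
    varying = {n: np.asarray(scalars[n], dtype=float) for n in names
               if not np.allclose(scalars[n], np.ravel(scalars[n])[0])}
    rhats: dict[str, float] = {}
    esses: dict[str, float] = {}
    if varying:
        ds = az.convert_to_dataset(varying)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if not single_chain:
                r_ds = az.rhat(ds)
                rhats = {n: float(r_ds[n]) for n in varying}
            e_ds = az.ess(ds)
            esses = {n: float(e_ds[n]) for n in varying}
    rows = []
    flagged = []
    for name in names:
        arr = np.asarray(scalars[name], dtype=float)
        constant = name not in varying
        r = rhats.get(name, np.nan)
        e = esses.get(name, np.nan)
        if constant:
            flagged.append(name)
        elif np.isfinite(r) and r > RHAT_FLAG_THRESHOLD:
            flagged.append(name)
        rows.append({
            "parameter": name,
            "mean": float(arr.mean()),
            "sd": float(arr.std()),
            "rhat": r,
            "ess": e,
            "constant": constant,
        })
    table = pd.DataFrame(rows).set_index("parameter")
    acceptance = None
    if isinstance(draws, PosteriorDraws) and "acceptance_rates" in draws.meta:
        acceptance = pd.DataFrame(draws.meta["acceptance_rates"])
        acceptance.index.name = "chain"
    return DiagnosticsReport(table=table, acceptance=acceptance, flagged=flagged)
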