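"""Sloan neutral community model: occurrence frequency vs abundance.

The model predicts the frequency with which a taxon is detected across
local communities from its mean relative abundance p in the metacommunity:

    F(p) = 1 - I_d(N*m*p, N*m*(1-p))

where I is the regularized incomplete beta CDF, N the community size (mean
sample depth), m the migration rate and d = 1/N the detection limit. m is
the single free parameter, fitted by nonlinear least squares of F(p_i)
against the observed detection frequencies f_i. Taxa are partitioned
against the 95% Wilson band around the prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from ecoassembly.containers import OtuTable

__all__ = ["NeutralCommunityModel", "NCMResults", "sloan_frequency"]


def sloan_frequency(p, m: float, N: float) -> np.ndarray:
    """Predicted detection frequency F(p) at migration rate m, depth N.

    Monotone increasing in p for fixed (m, N); approaches 1 as the beta
    mass moves above the detection limit d = 1/N.
    """
    p = np.asarray(p, dtype=float)
    d = 1.0 / N
    a = N * m * p
    b = N * m * (1.0 - p)
    out = np.empty_like(p)
    ok = (a > 0) & (b > 0)
    out[ok] = 1.0 - special.betainc(a[ok], b[ok], d)
    out[p <= 0] = 0.0
    out[p >= 1] = 1.0
    return out


def _wilson_band(freq_pred: np.ndarray, n: int, z: float = 1.959963984540054):
    """Wilson score interval around predicted frequencies at n samples.

    Preferred over the normal approximation because predicted frequencies
    pile up near 0 and 1.
    """
    f = np.clip(freq_pred, 0.0, 1.0)
    denom = 1.0 + z**2 / n
    center = (f + z**2 / (2 * n)) / denom
    half = z * np.sqrt(f * (1 - f) / n + z**2 / (4 * n**2)) / denom
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


class NeutralCommunityModel:
    """Fit the Sloan neutral model to an OTU table.

    Parameters
    ----------
    table : OtuTable
        At least 5 samples and 10 taxa with nonzero occurrence.
    allow_m_gt_1 : bool
        Let the fitted dispersal parameter exceed its nominal domain (0, 1]
        instead of clipping at 1 with a warning. Some published fits report
        m > 1; the flag permits replicating such outputs.
    """

    def __init__(self, table: OtuTable, allow_m_gt_1: bool = False):
        if table.n_samples < 5:
            raise ValueError("need >= 5 samples to fit the neutral model")
        occ = (table.counts > 0).sum(axis=0)
        if int((occ > 0).sum()) < 10:
            raise ValueError("need >= 10 taxa with nonzero occurrence")
        self.table = table
        self.allow_m_gt_1 = allow_m_gt_1

    def fit(self) -> "NCMResults":
        table = self.table
        keep = (table.counts > 0).any(axis=0)
        counts = table.counts.loc[:, keep]
        n_samples = counts.shape[0]
        N = float(counts.sum(axis=1).mean())
        d = 1.0 / N
        rel = counts.div(counts.sum(axis=1), axis=0)
        p = rel.mean(axis=0).to_numpy()
        f = (counts > 0).mean(axis=0).to_numpy()

        upper_bound = np.inf if self.allow_m_gt_1 else 1.0

        def residuals(logm):
            return sloan_frequency(p, np.exp(logm[0]), N) - f

        best = optimize.least_squares(
            residuals, x0=[np.log(0.1)], bounds=([np.log(1e-6)], [np.log(1e4)])
        )
        if not best.success:
            raise RuntimeError(
                f"neutral model fit did not converge: {best.message}"
            )
        m = float(np.exp(best.x[0]))
        if m > upper_bound:
            warnings.warn(
                f"fitted m = {m:.4f} exceeds 1; clipped to 1 "
                "(pass allow_m_gt_1=True to keep the unconstrained value)"
            )
            m = 1.0
        if m <= 1e-6:
            warnings.warn("fitted m at lower bound 1e-6")
            m = 1e-6

        pred = sloan_frequency(p, m, N)
        sse = float(((f - pred) ** 2).sum())
        sst = float(((f - f.mean()) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else float("nan")
        lower, upper = _wilson_band(pred, n_samples)
        partition = np.where(
            f > upper, "above", np.where(f < lower, "below", "within")
        )
        taxa = pd.DataFrame(
            {
                "mean_relative_abundance": p,
                "observed_frequency": f,
                "predicted_frequency": pred,
                "lower_95": lower,
                "upper_95": upper,
                "partition": partition,
            },
            index=counts.columns,
        )
        return NCMResults(
            m=m,
            N=N,
            Nm=N * m,
            r_squared=r2,
            detection_limit=d,
            n_samples=n_samples,
            taxa=taxa,
        )


@dataclass
class NCMResults:
    """Fitted migration rate, goodness of fit, and the per-taxon partition."""

    m: float
    N: float
    Nm: float
    r_squared: float
    detection_limit: float
    n_samples: int
    taxa: pd.DataFrame = field(repr=False)

    @property
    def fraction_within(self) -> float:
        return float((self.taxa["partition"] == "within").mean())

    @property
    def partition_fractions(self) -> pd.Series:
        return (
            self.taxa["partition"]
            .value_counts(normalize=True)
            .reindex(["above", "within", "below"], fill_value=0.0)
        )

    def summary(self) -> str:
        pf = self.partition_fractions
        return "\n".join(
            [
                "Sloan neutral community model",
                f"  samples: {self.n_samples}   taxa: {len(self.taxa)}",
                f"  m = {self.m:.4f}   Nm = {self.Nm:.1f}   "
                f"R^2 = {self.r_squared:.4f}",
                f"  within 95% band: {100 * pf['within']:.2f}%   "
                f"above: {100 * pf['above']:.2f}%   "
                f"below: {100 * pf['below']:.2f}%",
            ]
        )
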