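"""Mutual information between the bottleneck variable and auxiliary
coordinates; critical-feature ranking.

Coordinates (residue backbone dihedrals in the protein application) that
share high mutual information with the learned bottleneck are the ones
whose perturbation is most likely to disturb the slow process; ranking
features by max MI against either of a residue's two dihedrals therefore
flags candidate critical residues.

Estimator: plug-in MI on a 2D weighted histogram (quantile bin edges on
the bottleneck axis, fixed-width periodic edges for angles) with
Miller--Madow small-sample correction, clipped at zero.  When frames come
from a biased ensemble, reweighting to the unbiased ensemble is applied by
default through the per-frame weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reweighting import kish_ess

__all__ = ["MIRanking", "mutual_information", "rank_features"]


def _edges(x: np.ndarray, bins: int, periodic: bool, quantile: bool) -> np.ndarray:
    if periodic:
        return np.linspace(-np.pi, np.pi, bins + 1)
    if quantile:
        e = np.quantile(x, np.linspace(0, 1, bins + 1))
        e[0] -= 1e-12
        e[-1] += 1e-12
        # collapse duplicate quantiles (heavy ties) to strictly increasing edges
        e = np.unique(e)
        if e.size < 3:
            e = np.linspace(x.min() - 1e-12, x.max() + 1e-12, bins + 1)
        return e
    return np.linspace(x.min() - 1e-12, x.max() + 1e-12, bins + 1)


def mutual_information(x_series: np.ndarray, y_series: np.ndarray,
                       weights: np.ndarray | None = None, bins: int = 30,
                       y_periodic: bool = False, x_periodic: bool = False,
                       x_quantile: bool = True) -> float:
    """Histogram mutual information I(x; y) in nats, bias-corrected.

    ``weights`` are importance weights (e.g. exp(beta V)) reweighting a
    biased sample to the unbiased ensemble; the Miller--Madow correction
    uses the Kish effective sample size.  Constant inputs give 0 with a
    degeneracy warning.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: mutual information degenerates to 0",
                      stacklevel=2)
        return 0.0
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)

    ex = _edges(x, bins, x_periodic, x_quantile)
    ey = _edges(y, bins, y_periodic, x_quantile and not y_periodic)
    h, _, _ = np.histogram2d(x, y, bins=[ex, ey], weights=w)
    p = h / h.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    pxy = (px[:, None] * py[None, :])[nz]
    mi = float(np.sum(p[nz] * (np.log(p[nz]) - np.log(pxy))))
    # Miller--Madow: H_mm = H + (K-1)/(2N) per entropy term
    n_eff = kish_ess(w)
    kx = int(np.count_nonzero(px))
    ky = int(np.count_nonzero(py))
    kxy = int(np.count_nonzero(p))
    mi += ((kx - 1) + (ky - 1) - (kxy - 1)) / (2.0 * n_eff)
    return max(mi, 0.0)


@dataclass
class MIRanking:
    """Features ranked by their maximal MI with the bottleneck."""

    entries: list[tuple[str, float, float, float]]  # label, mi_phi, mi_psi, mi_max
    bins: int = 30
    reweighted: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries,
                            columns=["label", "mi_phi", "mi_psi", "mi_max"])

    @property
    def labels(self) -> list[str]:
        return [e[0] for e in self.entries]


def rank_features(pib_series, feature_table: dict, weights: np.ndarray | None = None,
                  bins: int = 30) -> MIRanking:
    """Rank labeled (phi, psi) angle pairs by max MI with the bottleneck.

    Parameters
    ----------
    pib_series : (M,) array or (M, 2) array
        Bottleneck time series; with two components (chi1, chi2) the MI is
        maximized over components.
    feature_table : mapping label -> (phi_series, psi_series)
        Two periodic angle series per feature, aligned with the bottleneck.
    weights : array, optional
        Importance weights reweighting to the unbiased ensemble.
    """
    pib = np.asarray(pib_series, dtype=float)
    if pib.ndim == 1:
        pib = pib[:, None]
    m = pib.shape[0]
    entries = []
    for label, (phi, psi) in feature_table.items():
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        if phi.shape[0] != m or psi.shape[0] != m:
            raise ValueError(f"feature {label!r} is not aligned with the PIB series")
        mi_phi = max(mutual_information(pib[:, c], phi, weights, bins,
                                        y_periodic=True)
                     for c in range(pib.shape[1]))
        mi_psi = max(mutual_information(pib[:, c], psi, weights, bins,
                                        y_periodic=True)
                     for c in range(pib.shape[1]))
        entries.append((label, mi_phi, mi_psi, max(mi_phi, mi_psi)))
    # stable descending sort: ties keep input order
    entries.sort(key=lambda e: -e[3])
    return MIRanking(entries=entries, bins=bins, reweighted=weights is not None)
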