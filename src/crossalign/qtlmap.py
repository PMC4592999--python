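"""Haley–Knott regression LOD scores, genome scans and eQTL classification.

Haley–Knott regression approximates standard interval mapping by regressing
the phenotype on the conditional genotype probabilities.  With probabilities
``p`` (n x 3, states BB/BR/RR) the QTL design is ``[1, p_BR, p_RR]`` (contrast
coding against the BB baseline; any full-rank recoding gives the same fit) and

    LOD = (n / 2) * log10(RSS_0 / RSS_1),

where ``RSS_0`` is the residual sum of squares under the null design (intercept
plus any covariates) and ``RSS_1`` under the QTL design (plus covariates and,
for an interactive covariate, covariate x genotype product columns).  Designs
are solved by least-norm least squares so collinear columns degrade gracefully
instead of failing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genoprob import GenoProbArray

logger = logging.getLogger("crossalign")


def normal_quantiles(y: np.ndarray) -> np.ndarray:
    """Rank-based transform of ``y`` to normal quantiles.

    Non-missing values are converted to ranks R (average ranks on ties) and
    replaced by ``Phi^{-1}((R - 0.5) / n)`` with ``n`` the non-missing count;
    NaNs are preserved.
    """
    y = np.asarray(y, dtype=float)
    out = np.full(y.shape, np.nan)
    obs = np.isfinite(y)
    n = int(obs.sum())
    if n == 0:
        return out
    ranks = stats.rankdata(y[obs], method="average")
    out[obs] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _designs(
    p: np.ndarray, covariates: np.ndarray | None, interactive: bool
) -> tuple[np.ndarray, np.ndarray]:
    n = p.shape[0]
    ones = np.ones((n, 1))
    geno = p[:, 1:3]  # (p_BR, p_RR) vs BB baseline
    if covariates is None:
        X0 = ones
        X1 = np.hstack([ones, geno])
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        X0 = np.hstack([ones, cov])
        cols = [ones, geno, cov]
        if interactive:
            cols += [cov[:, [j]] * geno for j in range(cov.shape[1])]
        X1 = np.hstack(cols)
    return X0, X1


def hk_lod(
    y: np.ndarray,
    p: np.ndarray,
    covariates: np.ndarray | None = None,
    interactive: bool = False,
) -> float:
    """Haley–Knott LOD at a single position.

    ``y`` may contain NaNs (those samples are dropped, along with their rows
    of ``p`` and covariates).  A perfect fit (RSS_1 = 0) returns +inf with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    obs = np.isfinite(y)
    y = y[obs]
    p = p[obs]
    cov = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != obs.shape[0]:
            cov = cov.T
        cov = cov[obs]
    n = y.size
    X0, X1 = _designs(p, cov, interactive)
    if n < X1.shape[1]:
        raise ValueError(f"only {n} observations for {X1.shape[1]} design columns")
    rss0 = _rss(y, X0)
    rss1 = _rss(y, X1)
    if rss0 <= 0:  # constant phenotype: both models fit exactly
        return 0.0
    if rss1 <= 1e-10 * rss0:  # numerically perfect fit
        warnings.warn("perfect fit under the QTL model: LOD is +inf", stacklevel=2)
        return float("inf")
    return max(0.0, (n / 2.0) * np.log10(rss0 / rss1))


@dataclass
class ScanResult:
    """LOD scores along one chromosome with the peak and its support interval."""

    chromosome: str
    positions: np.ndarray  # cM
    lod: np.ndarray
    peak_index: int
    peak_position: float
    peak_lod: float
    interval: tuple[float, float]  # 2-LOD support interval, cM

    def to_records(self) -> list[dict]:
        return [
            {"chromosome": self.chromosome, "position": float(p), "lod": float(l)}
            for p, l in zip(self.positions, self.lod)
        ]


def _support_interval(
    positions: np.ndarray, lod: np.ndarray, peak: int, drop: float = 2.0
) -> tuple[float, float]:
    """Contiguous run around the peak with LOD > peak - drop, extended one
    grid position outward on each side when possible."""
    lo = peak
    while lo > 0 and lod[lo - 1] > lod[peak] - drop:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] > lod[peak] - drop:
        hi += 1
    lo = max(0, lo - 1)
    hi = min(len(lod) - 1, hi + 1)
    return float(positions[lo]), float(positions[hi])


def scan_chromosome(
    y: np.ndarray,
    probs: GenoProbArray,
    chromosome: str,
    covariates: np.ndarray | None = None,
    interactive: bool = False,
) -> ScanResult:
    """Haley–Knott LOD at every grid position of one chromosome.

    The peak breaks ties toward the lower position; the 2-LOD support interval
    is the contiguous run around the peak with LOD above peak - 2, extended by
    one flanking grid position on each side.
    """
    post = probs.probs[chromosome]
    positions = probs.grid.positions[chromosome]
    lod = np.array(
        [hk_lod(y, post[:, k, :], covariates, interactive) for k in range(post.shape[1])]
    )
    peak = int(np.argmax(lod))  # first index on ties
    return ScanResult(
        chromosome=chromosome,
        positions=positions,
        lod=lod,
        peak_index=peak,
        peak_position=float(positions[peak]),
        peak_lod=float(lod[peak]),
        interval=_support_interval(positions, lod, peak),
    )


def classify_eqtl(
    scan: ScanResult,
    probe_chromosome: str,
    probe_position_cM: float,
    lod_threshold: float = 5.0,
) -> str:
    """Call a scan peak 'none', 'local' or 'trans' relative to the probe location.

    A QTL is inferred when the peak LOD strictly exceeds ``lod_threshold``;
    it is local when the scan is on the probe's own chromosome and the 2-LOD
    support interval contains the probe position, trans otherwise.  Probes
    with unknown location must be filtered by the caller.
    """
    if probe_chromosome is None or not np.isfinite(probe_position_cM):
        raise ValueError("probe location unknown; filter such probes before calling")
    if not scan.peak_lod > lod_threshold:
        return "none"
    if scan.chromosome == probe_chromosome:
        lo, hi = scan.interval
        if lo <= probe_position_cM <= hi:
            return "local"
    return "trans"


def write_scan(scan: ScanResult, tsv_path, json_path=None) -> None:
    """TSV of (chromosome, position, LOD) plus an optional JSON peak summary."""
    import json as _json

    import pandas as pd

    pd.DataFrame(scan.to_records()).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        summary = {
            "chromosome": scan.chromosome,
            "peak_position": scan.peak_position,
            "peak_lod": scan.peak_lod,
            "interval": list(scan.interval),
        }
        with open(json_path, "w") as fh:
            _json.dump(summary, fh, indent=1)
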