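"""6mA site calling from inter-pulse-duration kinetics.

The site-level IPD ratio is the exponential of the mean log IPD shift over
molecules. Methylated fractions come from a two-component Gaussian mixture on
per-molecule mean log IPD, with component means fixed at mu0 (unmethylated)
and mu0 + delta (methylated) and only the mixing weight estimated by EM.
Called sites satisfy coverage >= 20 and IPD ratio >= 4; records failing those
filters but with coverage >= 11 form the null set used as the motif
background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .types import KineticSite, MoleculeObservation, SiteKey, SiteSet


@dataclass
class CallingParams:
    """Thresholds and kinetic-model parameters for site calling.

    ``min_coverage``/``min_ipd_ratio`` define called sites (both inclusive);
    ``null_min_coverage`` is the coverage floor for the failed-filter null
    set. ``mu0``/``sigma`` are the unmethylated log-IPD mean and per-pass
    standard deviation; ``delta`` the methylation shift in log IPD.
    """

    min_coverage: int = 20
    min_ipd_ratio: float = 4.0
    null_min_coverage: int = 11
    mu0: float = 0.0
    sigma: float = 0.5
    delta: float = math.log(16.0)

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.min_ipd_ratio <= 0:
            raise ValueError("min_ipd_ratio must be > 0")
        if self.null_min_coverage > self.min_coverage:
            raise ValueError("null_min_coverage must be <= min_coverage")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def compute_ipd_ratio(
    observations: Sequence[MoleculeObservation] | Sequence[float],
    mu0: float = 0.0,
) -> float:
    """Site IPD ratio: exp(mean over molecules of mean log IPD, minus mu0)."""
    vals = _mean_log_ipds(observations)
    if vals.size == 0:
        raise ValueError("need at least one molecule observation")
    return float(np.exp(vals.mean() - mu0))


def _mean_log_ipds(observations) -> np.ndarray:
    if len(observations) and isinstance(observations[0], MoleculeObservation):
        return np.array([o.mean_log_ipd for o in observations], dtype=float)
    return np.asarray(observations, dtype=float)


def _n_passes(observations, n: int) -> np.ndarray:
    if len(observations) and isinstance(observations[0], MoleculeObservation):
        return np.array([o.n_passes for o in observations], dtype=float)
    return np.ones(n)


def estimate_methylated_fraction(
    observations: Sequence[MoleculeObservation] | Sequence[float],
    params: CallingParams,
    n_passes: Sequence[int] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> Tuple[float, int]:
    """Estimate the methylated fraction at one site from molecule kinetics.

    Fits a two-component normal mixture on per-molecule mean log IPD with
    fixed component means (mu0, mu0 + delta) and per-molecule variance
    sigma^2 / n_passes; only the mixing weight is free and is estimated by
    EM. Returns (fraction, methylated molecule count), the count being the
    round-half-up of fraction * coverage.
    """
    x = _mean_log_ipds(observations)
    if x.size == 0:
        raise ValueError("need at least one molecule observation")
    if params.sigma <= 0:
        raise ValueError("sigma must be > 0")
    npass = (
        np.asarray(n_passes, dtype=float)
        if n_passes is not None
        else _n_passes(observations, x.size)
    )
    var = params.sigma**2 / npass
    # Log densities under each fixed-mean component.
    ll0 = -0.5 * (x - params.mu0) ** 2 / var
    ll1 = -0.5 * (x - params.mu0 - params.delta) ** 2 / var
    w = 0.5
    for _ in range(max_iter):
        # E step: responsibility of the methylated component.
        log_num = np.log(w) + ll1
        log_den = np.logaddexp(np.log1p(-w) + ll0, log_num) if 0 < w < 1 else None
        if w <= 0:
            r = np.zeros_like(x)
        elif w >= 1:
            r = np.ones_like(x)
        else:
            r = np.exp(log_num - log_den)
        w_new = float(r.mean())
        if abs(w_new - w) < tol:
            w = w_new
            break
        w = w_new
    else:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(n={x.size}, last weight {w:.6f})"
        )
    fraction = min(1.0, max(0.0, w))
    return fraction, methylated_cell_count(fraction, x.size)


def moment_fraction(ipd_ratio: float, delta: float) -> float:
    """Method-of-moments fraction estimate f = (ratio - 1) / (e^delta - 1).

    Fallback when per-molecule observations are unavailable; clamped to
    [0, 1].
    """
    f = (ipd_ratio - 1.0) / (math.exp(delta) - 1.0)
    return min(1.0, max(0.0, f))


def methylated_cell_count(fraction: float, coverage: int) -> int:
    """Methylated molecule count = round-half-up of fraction * coverage."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    return min(coverage, int(math.floor(fraction * coverage + 0.5)))


def filter_sites(sites: SiteSet, params: CallingParams | None = None) -> Tuple[SiteSet, SiteSet]:
    """Partition candidate records into (called, null) site sets.

    Called: coverage >= min_coverage and IPD ratio >= min_ipd_ratio.
    Null: fails the called criteria but has coverage >= null_min_coverage
    (the failed-filter background for motif testing). Records below the null
    coverage floor are discarded. The partition is order independent and
    idempotent.
    """
    params = params or CallingParams()
    called: List[KineticSite] = []
    null: List[KineticSite] = []
    for s in sites:
        if s.coverage >= params.min_coverage and s.ipd_ratio >= params.min_ipd_ratio:
            called.append(s)
        elif s.coverage >= params.null_min_coverage:
            null.append(s)
    return SiteSet(called), SiteSet(null)


def call_from_molecules(
    molecules: Iterable[MoleculeObservation],
    params: CallingParams | None = None,
    contexts: Dict[SiteKey, str] | None = None,
) -> SiteSet:
    """Summarise molecule observations into per-site kinetic records.

    Groups molecules by (chrom, pos, strand), computes coverage, IPD ratio
    and the EM methylated fraction per site, and attaches sequence contexts
    when provided. No filtering is applied; feed the result to
    :func:`filter_sites`.
    """
    params = params or CallingParams()
    by_site: Dict[SiteKey, List[MoleculeObservation]] = {}
    for m in molecules:
        by_site.setdefault(m.site_key, []).append(m)
    out: List[KineticSite] = []
    for key in sorted(by_site):
        obs = by_site[key]
        ratio = compute_ipd_ratio(obs, params.mu0)
        fraction, _ = estimate_methylated_fraction(obs, params)
        chrom, pos, strand = key
        out.append(
            KineticSite(
                chrom=chrom,
                pos=pos,
                strand=strand,
                coverage=len(obs),
                ipd_ratio=ratio,
                meth_fraction=fraction,
                context=contexts.get(key) if contexts else None,
            )
        )
    return SiteSet(out)
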