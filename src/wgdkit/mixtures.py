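"""Mixture modeling of Ks distributions and anchor-pair filtering.

Two model families are fitted by (weighted) expectation–maximization:

* ``gmm_log`` — a Gaussian mixture on ln(Ks); each component is a lognormal
  on the Ks scale, with mode ("peak") exp(log_mean - log_sd^2).
* ``elmm``    — an exponential background (small-scale duplications whose
  survivorship decays with age) plus up to five lognormal components (WGD
  peaks), fitted directly on the Ks scale.

Data points may carry weights (node-weighted distributions); weights enter
every EM sum. Model order is selected by BIC (or AIC), and anchor pairs
falling inside the central quantile interval of a chosen lognormal
component — optionally truncated at a Ks saturation cutoff — are retained
for absolute dating.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm as _norm

from .formats import SequenceRecord, write_fasta
from .ksdist import WeightedKsDistribution

_LOG_SD_FLOOR = 1e-3


@dataclass
class LognormalComponent:
    weight: float
    log_mean: float
    log_sd: float

    @property
    def peak(self) -> float:
        """Mode of the lognormal on the Ks scale."""
        return float(np.exp(self.log_mean - self.log_sd ** 2))


@dataclass
class MixtureFit:
    kind: str  # "gmm_log" or "elmm"
    components: list[LognormalComponent]
    exp_rate: float | None
    exp_weight: float
    loglik: float
    bic: float
    aic: float
    n_used: int
    converged: bool
    n_iter: int
    loglik_history: list[float] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def k(self) -> int:
        return len(self.components)


def _prepare(ks: WeightedKsDistribution | Sequence[float],
             weights: Sequence[float] | None = None):
    if isinstance(ks, WeightedKsDistribution):
        x = ks.values
        w = ks.weights
    else:
        x = np.asarray(ks, dtype=float)
        w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    keep = np.isfinite(x) & (x > 0)
    n_excluded = int(len(x) - keep.sum())
    return x[keep], w[keep], n_excluded


def _free_params(kind: str, k: int) -> int:
    if kind == "gmm_log":
        return 3 * k - 1  # k means, k sds, k-1 free weights
    return 3 * k + 1  # + exp rate and its weight


def _lognorm_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    lx = np.log(x)
    return (-0.5 * ((lx - mu) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi)) - lx)


def _quantile_means(lx: np.ndarray, w: np.ndarray, k: int, jitter: float,
                    rng: np.random.Generator) -> np.ndarray:
    qs = np.linspace(0, 100, k + 2)[1:-1]
    mus = np.percentile(lx, qs)
    return mus + rng.normal(0, jitter, size=k)


def _em_gmm_log(x, w, k, seed, tol, max_iter, n_init):
    lx = np.log(x)
    wsum = w.sum()
    best = None
    rng = np.random.default_rng(seed)
    for init in range(n_init):
        mus = _quantile_means(lx, w, k, 0.0 if init == 0 else 0.3, rng)
        var0 = max(float(np.cov(lx, aweights=w)) if len(lx) > 1 else 1.0, 1e-4)
        sds = np.full(k, np.sqrt(var0))
        pis = np.full(k, 1.0 / k)
        ll_prev = -np.inf
        history = []
        converged = False
        for it in range(max_iter):
            logp = np.vstack([
                np.log(pis[j]) + _norm.logpdf(lx, mus[j], sds[j]) for j in range(k)
            ])
            m = logp.max(axis=0)
            lse = m + np.log(np.exp(logp - m).sum(axis=0))
            ll = float(np.sum(w * lse))
            history.append(ll)
            resp = np.exp(logp - lse)
            wr = resp * w  # (k, n)
            nk = wr.sum(axis=1)
            pis = nk / wsum
            mus = (wr @ lx) / nk
            sds = np.sqrt(np.maximum(
                np.array([(wr[j] @ (lx - mus[j]) ** 2) / nk[j] for j in range(k)]),
                _LOG_SD_FLOOR ** 2))
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        if best is None or history[-1] > best[0]:
            best = (history[-1], mus.copy(), sds.copy(), pis.copy(), converged,
                    len(history), history)
    ll, mus, sds, pis, converged, n_iter, history = best
    order = np.argsort(mus)
    comps = [LognormalComponent(float(pis[j]), float(mus[j]), float(sds[j]))
             for j in order]
    # the fitted density lives on ln(Ks); report the likelihood on the Ks
    # scale (Jacobian term) so GMM and ELMM criteria are comparable
    ll_ks = ll - float(np.sum(w * np.log(x)))
    return comps, ll_ks, converged, n_iter, history


def fit_gmm_log(ks: WeightedKsDistribution | Sequence[float],
                k_range: Iterable[int] = (1, 2, 3, 4, 5),
                weights: Sequence[float] | None = None,
                n_init: int = 5, seed: int = 0, tol: float = 1e-6,
                max_iter: int = 500) -> list[MixtureFit]:
    """Weighted EM Gaussian mixtures on ln(Ks), one fit per k in ``k_range``."""
    x, w, n_excluded = _prepare(ks, weights)
    fits = []
    n_used = len(x)
    for k in k_range:
        if n_used < 5 * k:
            warnings.warn(f"too few values ({n_used}) for k={k}; skipped")
            continue
        if np.ptp(x) == 0:
            warnings.warn("degenerate input: all Ks values identical")
            comp = LognormalComponent(1.0, float(np.log(x[0])), _LOG_SD_FLOOR)
            fits.append(MixtureFit("gmm_log", [comp], None, 0.0, 0.0, 0.0, 0.0,
                                   n_used, True, 0, [], n_excluded))
            continue
        comps, ll, converged, n_iter, history = _em_gmm_log(
            x, w, k, seed + k, tol, max_iter, n_init)
        p = _free_params("gmm_log", k)
        fits.append(MixtureFit(
            kind="gmm_log", components=comps, exp_rate=None, exp_weight=0.0,
            loglik=ll, bic=-2 * ll + p * math.log(n_used),
            aic=-2 * ll + 2 * p, n_used=n_used, converged=converged,
            n_iter=n_iter, loglik_history=history, n_excluded=n_excluded))
    return fits


def _em_elmm(x, w, m, seed, tol, max_iter, n_init):
    lx = np.log(x)
    wsum = w.sum()
    rng = np.random.default_rng(seed)
    best = None
    for init in range(n_init):
        rate = 1.0 / float(np.average(x, weights=w))
        if m > 0:
            mus = _quantile_means(lx, w, m, 0.0 if init == 0 else 0.3, rng)
            sds = np.full(m, 0.3)
            pis = np.full(m, 0.5 / m)
            pi0 = 0.5
        else:
            mus = np.empty(0)
            sds = np.empty(0)
            pis = np.empty(0)
            pi0 = 1.0
        ll_prev = -np.inf
        history = []
        converged = False
        for it in range(max_iter):
            logp = [np.log(pi0) + np.log(rate) - rate * x]
            for j in range(m):
                logp.append(np.log(pis[j]) + _lognorm_logpdf(x, mus[j], sds[j]))
            logp = np.vstack(logp)
            top = logp.max(axis=0)
            lse = top + np.log(np.exp(logp - top).sum(axis=0))
            ll = float(np.sum(w * lse))
            history.append(ll)
            resp = np.exp(logp - lse)
            wr = resp * w
            nk = wr.sum(axis=1)
            pi0 = nk[0] / wsum
            if nk[0] > 0:
                rate = nk[0] / float(wr[0] @ x)
            for j in range(m):
                pis[j] = nk[j + 1] / wsum
                if nk[j + 1] > 0:
                    mus[j] = (wr[j + 1] @ lx) / nk[j + 1]
                    sds[j] = max(np.sqrt((wr[j + 1] @ (lx - mus[j]) ** 2) / nk[j + 1]),
                                 _LOG_SD_FLOOR)
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        if best is None or history[-1] > best[0]:
            best = (history[-1], rate, mus.copy(), sds.copy(), pis.copy(), pi0,
                    converged, len(history), history)
    ll, rate, mus, sds, pis, pi0, converged, n_iter, history = best
    order = np.argsort(mus)
    comps = [LognormalComponent(float(pis[j]), float(mus[j]), float(sds[j]))
             for j in order]
    return comps, float(rate), float(pi0), ll, converged, n_iter, history


def fit_elmm(ks: WeightedKsDistribution | Sequence[float],
             max_lognormals: int = 5,
             weights: Sequence[float] | None = None,
             n_init: int = 5, seed: int = 0, tol: float = 1e-6,
             max_iter: int = 500) -> list[MixtureFit]:
    """Exponential + up to ``max_lognormals`` lognormal components via EM.

    Returns one fit per number of lognormal components m = 0..max_lognormals.
    """
    x, w, n_excluded = _prepare(ks, weights)
    if len(x) == 0:
        raise ValueError("no positive Ks values to fit")
    fits = []
    n_used = len(x)
    for m in range(max_lognormals + 1):
        if n_used < 5 * (m + 1):
            warnings.warn(f"too few values ({n_used}) for m={m}; skipped")
            continue
        comps, rate, pi0, ll, converged, n_iter, history = _em_elmm(
            x, w, m, seed + m, tol, max_iter, n_init)
        if not converged:
            warnings.warn(f"ELMM with m={m} did not converge; best-so-far returned")
        p = _free_params("elmm", m)
        fits.append(MixtureFit(
            kind="elmm", components=comps, exp_rate=rate, exp_weight=pi0,
            loglik=ll, bic=-2 * ll + p * math.log(n_used),
            aic=-2 * ll + 2 * p, n_used=n_used, converged=converged,
            n_iter=n_iter, loglik_history=history, n_excluded=n_excluded))
    return fits


def select_model(fits: Sequence[MixtureFit], criterion: str = "bic") -> MixtureFit:
    """Lowest-criterion fit among converged fits; ties go to fewer components."""
    conv = [f for f in fits if f.converged]
    if not conv:
        diag = ", ".join(f"{f.kind}(k={f.k}, iter={f.n_iter})" for f in fits)
        raise RuntimeError(f"no converged fits to select from: {diag}")
    key = (lambda f: (f.bic, f.k)) if criterion == "bic" else (lambda f: (f.aic, f.k))
    return min(conv, key=key)


@dataclass
class PeakFilter:
    component: LognormalComponent
    level: float
    interval: tuple[float, float]
    ks_cutoff: float
    retained: list
    n_input: int

    @property
    def retained_fraction(self) -> float:
        return len(self.retained) / self.n_input if self.n_input else 0.0


def filter_anchors(anchor_ks: Sequence[tuple[object, float]],
                   fit: MixtureFit, component_index: int = 0,
                   level: float = 0.95, ks_cutoff: float = 3.0) -> PeakFilter:
    """Retain anchor pairs inside the central ``level`` quantile interval of
    one fitted lognormal component, truncated above at ``ks_cutoff``."""
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    comp = fit.components[component_index]
    z = float(_norm.ppf(0.5 + level / 2.0))
    lo = float(np.exp(comp.log_mean - z * comp.log_sd))
    hi = float(np.exp(comp.log_mean + z * comp.log_sd))
    hi_eff = min(hi, ks_cutoff)
    if hi_eff <= lo:
        raise ValueError(
            f"confidence interval ({lo:.4f}, {hi:.4f}) lies entirely above the "
            f"Ks cutoff {ks_cutoff}; choose a younger component")
    retained = [(pid, ks) for pid, ks in anchor_ks if lo <= ks <= hi_eff]
    return PeakFilter(component=comp, level=level, interval=(lo, hi_eff),
                      ks_cutoff=ks_cutoff, retained=retained,
                      n_input=len(anchor_ks))


def export_dating_inputs(orthogroups, cds: Mapping[str, SequenceRecord],
                         species_tree: str, outdir: str | Path,
                         mcmc_settings: Mapping[str, str] | None = None) -> list[Path]:
    """Write per-orthogroup codon alignments, the calibrated species tree and
    a control-file template for an external molecular-dating engine.

    No dating engine is executed; the files are inputs for one.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups = list(orthogroups)
    if not groups:
        raise ValueError("no orthogroups to export")
    written: list[Path] = []
    skipped = 0
    for og in groups:
        members = og.members
        if any(g not in cds for g in members):
            warnings.warn(f"orthogroup {og.group_id} has members without CDS; skipped")
            skipped += 1
            continue
        path = outdir / f"{og.group_id}.aln.fasta"
        write_fasta([cds[g] for g in members], path)
        written.append(path)
    if not written:
        raise ValueError("no orthogroup could be exported (missing CDS)")
    tree_path = outdir / "dating_tree.nwk"
    tree_path.write_text(species_tree.strip() + "\n")
    written.append(tree_path)
    settings = {
        "model": "independent rates, lognormal",
        "burnin": "2000",
        "iterations": "20000000",
        "sampfreq": "1000",
    }
    if mcmc_settings:
        settings.update(mcmc_settings)
    ctl = outdir / "dating_control.template.ctl"
    lines = ["# control-file template for an external dating engine",
             f"treefile = {tree_path.name}",
             "seqfiles = " + " ".join(p.name for p in written if p.suffix == ".fasta")]
    lines += [f"{k} = {v}" for k, v in sorted(settings.items())]
    ctl.write_text("\n".join(lines) + "\n")
    written.append(ctl)
    return written
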