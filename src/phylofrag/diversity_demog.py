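"""Genomic diversity and demography summaries.

Percentage pairwise distance doubles as nucleotide diversity (pi, within a
species) and divergence (Dxy, between species).  Per-sample heterozygosity
is summarized in non-overlapping windows (default 200 kb) by mean and
interquartile range.  Runs of homozygosity are segmented with a two-state
HMM over windowed het counts: emissions are Binomial(callable, theta_state)
with the ROH-state rate fixed at a prior (default 2e-4 per bp) and the
background rate re-estimated by EM; windows whose posterior probability of
the ROH state passes a cutoff form segments, and heterozygosity is
re-estimated inside and outside them.  Split times between recently
diverged populations come from the relative cross-coalescence rate (rCCR),
taking the time where the series first crosses half of its maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp

from .msc_sim import DiploidGenotypes
from .treebuild import DistanceMatrix


# ---------------------------------------------------------------------------
# pi / Dxy


@dataclass
class DiversityMatrix:
    """Pairwise percentage distances labeled pi (within) or Dxy (between)."""

    labels: list[str]
    percent: np.ndarray
    kind: np.ndarray  # object array: "pi" | "Dxy" | ""

    def table(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                rows.append({"sample1": self.labels[i],
                             "sample2": self.labels[j],
                             "percent_distance": self.percent[i, j],
                             "kind": self.kind[i, j]})
        return pd.DataFrame(rows)


def pi_dxy(d: DistanceMatrix, species_map: dict[str, str]) -> DiversityMatrix:
    """Label percentage distances as pi (conspecific) or Dxy (heterospecific)."""
    for lab in d.labels:
        if lab not in species_map:
            raise ValueError(f"sample {lab!r} has no species assignment")
    pct = d.distances() * 100.0
    n = d.n
    kind = np.empty((n, n), dtype=object)
    kind[:] = ""
    for i in range(n):
        for j in range(n):
            if i != j:
                same = species_map[d.labels[i]] == species_map[d.labels[j]]
                kind[i, j] = "pi" if same else "Dxy"
    return DiversityMatrix(list(d.labels), pct, kind)


# ---------------------------------------------------------------------------
# windowed heterozygosity


@dataclass
class HetTrack:
    """Windowed heterozygous and callable site counts for one sample."""

    chrom: str
    window: int
    starts: np.ndarray
    het: np.ndarray
    callable_sites: np.ndarray

    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.callable_sites > 0,
                            self.het / np.maximum(self.callable_sites, 1),
                            np.nan)

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def window_heterozygosity(g: DiploidGenotypes, window: int = 200_000
                          ) -> tuple[HetTrack, float, float]:
    """Per-window het rate plus genome mean and interquartile range.

    Windows with zero callable sites are flagged (NaN rate) and excluded
    from the summaries.
    """
    length = g.length
    n_win = length // window if length % window == 0 else length // window + 1
    starts = np.arange(n_win) * window
    het_site = (g.genotypes == 1) & g.callable_mask
    idx = np.arange(length) // window
    het = np.bincount(idx, weights=het_site.astype(float), minlength=n_win)
    cal = np.bincount(idx, weights=g.callable_mask.astype(float),
                      minlength=n_win)
    track = HetTrack(g.chrom, window, starts, het, cal)
    rates = track.rates()
    ok = ~np.isnan(rates)
    mean = float(np.mean(rates[ok])) if ok.any() else float("nan")
    q25, q75 = (np.percentile(rates[ok], [25, 75]) if ok.any()
                else (float("nan"),) * 2)
    return track, mean, float(q75 - q25)


# ---------------------------------------------------------------------------
# ROH HMM


@dataclass
class RohResult:
    """HMM segmentation of the genome into ROH and background states."""

    segments: list[tuple[str, int, int, float]]  # chrom, start, end, mean PP
    roh_fraction: float
    het_inside: float
    het_outside: float
    theta_roh: float
    theta_bg: float
    switch_prob: float
    posteriors: np.ndarray  # P(ROH) per window


def _binom_logpmf(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    p = min(max(p, 1e-300), 1 - 1e-12)
    return (-betaln(k + 1, n - k + 1) - np.log(n + 1)
            + k * math.log(p) + (n - k) * math.log1p(-p))


def roh_hmm(t: HetTrack, theta_roh: float = 0.0002,
            switch_prob: float = 0.01, posterior_cutoff: float = 0.9,
            max_iter: int = 50, tol: float = 1e-6) -> RohResult:
    """Two-state (ROH / background) HMM over windowed het counts.

    Emissions are Binomial(callable, theta_state); ``theta_roh`` stays
    fixed at its prior while the background rate is re-estimated by EM
    from the forward-backward state posteriors.  Maximal runs of windows
    with P(ROH) >= ``posterior_cutoff`` become segments.
    """
    if t.n_windows < 2:
        raise ValueError("need at least 2 windows")
    k = np.asarray(t.het, dtype=float)
    n = np.asarray(t.callable_sites, dtype=float)
    w = t.n_windows

    tot_het, tot_cal = k.sum(), n.sum()
    theta_bg = tot_het / tot_cal if tot_cal else 0.0
    if theta_bg <= theta_roh:
        raise ValueError(
            f"estimated background rate {theta_bg:.3g} does not exceed the "
            f"ROH prior {theta_roh:.3g}; states are not separable")

    log_trans = np.log(np.array([[1 - switch_prob, switch_prob],
                                 [switch_prob, 1 - switch_prob]]))
    log_init = np.log(np.array([0.5, 0.5]))

    def forward_backward(theta_bg):
        logb = np.stack([_binom_logpmf(k, n, theta_roh),
                         _binom_logpmf(k, n, theta_bg)], axis=1)
        logb[n == 0] = 0.0  # uncallable windows are uninformative
        la = np.zeros((w, 2))
        la[0] = log_init + logb[0]
        for i in range(1, w):
            la[i] = logb[i] + logsumexp(la[i - 1][:, None] + log_trans, axis=0)
        lb = np.zeros((w, 2))
        for i in range(w - 2, -1, -1):
            lb[i] = logsumexp(log_trans + (logb[i + 1] + lb[i + 1])[None, :],
                              axis=1)
        ll = float(logsumexp(la[-1]))
        post = la + lb
        post -= logsumexp(post, axis=1, keepdims=True)
        return np.exp(post), ll

    prev_ll = -np.inf
    for _ in range(max_iter):
        post, ll = forward_backward(theta_bg)
        gamma_bg = post[:, 1]
        denom = float((gamma_bg * n).sum())
        new_bg = float((gamma_bg * k).sum()) / denom if denom else theta_bg
        if abs(ll - prev_ll) < tol:
            theta_bg = max(new_bg, theta_roh * 1.0000001)
            break
        theta_bg = max(new_bg, theta_roh * 1.0000001)
        prev_ll = ll
    post, _ = forward_backward(theta_bg)
    p_roh = post[:, 0]

    in_roh = p_roh >= posterior_cutoff
    segments = []
    i = 0
    while i < w:
        if in_roh[i]:
            j = i
            while j + 1 < w and in_roh[j + 1]:
                j += 1
            start = int(t.starts[i])
            end = int(t.starts[j]) + t.window
            segments.append((t.chrom, start, end, float(p_roh[i:j + 1].mean())))
            i = j + 1
        else:
            i += 1

    total_bp = w * t.window
    roh_bp = sum(e - s for _, s, e, _ in segments)
    het_in = (k[in_roh].sum() / n[in_roh].sum()) if n[in_roh].sum() else float("nan")
    het_out = (k[~in_roh].sum() / n[~in_roh].sum()) if n[~in_roh].sum() else float("nan")
    return RohResult(segments, roh_bp / total_bp, float(het_in),
                     float(het_out), theta_roh, theta_bg, switch_prob, p_roh)


def roh_viterbi(t: HetTrack, theta_roh: float, theta_bg: float,
                switch_prob: float = 0.01) -> np.ndarray:
    """Viterbi path (True = ROH) for the same two-state model."""
    k = np.asarray(t.het, dtype=float)
    n = np.asarray(t.callable_sites, dtype=float)
    w = t.n_windows
    logb = np.stack([_binom_logpmf(k, n, theta_roh),
                     _binom_logpmf(k, n, theta_bg)], axis=1)
    logb[n == 0] = 0.0
    log_trans = np.log(np.array([[1 - switch_prob, switch_prob],
                                 [switch_prob, 1 - switch_prob]]))
    delta = np.zeros((w, 2))
    back = np.zeros((w, 2), dtype=int)
    delta[0] = math.log(0.5) + logb[0]
    for i in range(1, w):
        scores = delta[i - 1][:, None] + log_trans
        back[i] = scores.argmax(axis=0)
        delta[i] = logb[i] + scores.max(axis=0)
    path = np.zeros(w, dtype=int)
    path[-1] = delta[-1].argmax()
    for i in range(w - 2, -1, -1):
        path[i] = back[i + 1][path[i + 1]]
    return path == 0


# ---------------------------------------------------------------------------
# rCCR


@dataclass
class RateCurve:
    """Piecewise-constant coalescence-rate series over time segments."""

    left: np.ndarray
    right: np.ndarray
    rate: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if not (len(self.left) == len(self.right) == len(self.rate)):
            raise ValueError("segment arrays must align")
        if (np.diff(self.left) <= 0).any() or (self.right <= self.left).any():
            raise ValueError("time boundaries must increase")
        if (self.rate < 0).any():
            raise ValueError("rates must be non-negative")

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.left + self.right)


def rccr(within1: RateCurve, within2: RateCurve, cross: RateCurve
         ) -> RateCurve:
    """Relative cross-coalescence rate 2*lambda_cross/(lambda1+lambda2)."""
    for other in (within2, cross):
        if (len(other.left) != len(within1.left)
                or not np.allclose(within1.left, other.left)
                or not np.allclose(within1.right, other.right)):
            raise ValueError("rate curves must share their time segmentation")
    denom = within1.rate + within2.rate
    if (denom == 0).any():
        raise ZeroDivisionError("zero within-population rates in a segment")
    series = 2.0 * cross.rate / denom
    return RateCurve(within1.left, within1.right, series, label="rCCR")


def split_time_half_max(r: RateCurve) -> float:
    """Population split time: where the rCCR first crosses half its maximum.

    Scanning from the most recent segment toward the past, the first
    crossing of max/2 between consecutive segment midpoints is linearly
    interpolated.  A series that never crosses (e.g. constant) is an error.
    """
    y = r.rate
    x = r.midpoints()
    half = y.max() / 2.0
    for i in range(len(y) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - half) * (y1 - half) < 0 or (y0 != y1 and (y0 == half or y1 == half)):
            frac = (half - y0) / (y1 - y0)
            return float(x[i] + frac * (x[i + 1] - x[i]))
        if y0 == half and y1 == half:
            continue
    raise ValueError("no half-max crossing in the rCCR series")
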