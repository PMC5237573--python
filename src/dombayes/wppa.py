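"""Sliding-window posterior probability of association (WPPA).

One window is anchored at every panel SNP and spans a fixed genetic length
(half-open: a SNP belongs to the window if anchor <= position < anchor +
size), so there are as many windows as SNPs.  For every stored MCMC sample
the window genomic variance is

    sigma2_gw = sum_{j in w} [ H_j alpha_j^2 + H_j^2 d_j^2 ],

with H_j = 2 p_j q_j and alpha_j = a_j + (q_j - p_j) d_j (d_j = 0 for
BayesC samples).  Its expectation under an equal distribution of the total
genetic variance across the genome is

    E(sigma2_gw) = sum_{j in w} [ H_j E(alpha^2) + H_j^2 E(d^2) ],

with E(alpha^2) = v_a / sum_j H_j and E(d^2) = v_d / sum_j H_j^2 over the
whole panel, the unique normalisation for which the window expectations
tile to v_a + v_d genome-wide.  The same expectation (including the
dominance term) is used for BayesC and BayesD scans.  WPPA is the fraction
of stored samples with q_w = sigma2_gw / E(sigma2_gw) strictly above 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .bayes_mcmc import PosteriorSamples

__all__ = [
    "Window",
    "WindowScan",
    "sliding_windows",
    "window_genomic_variance",
    "expected_window_variance",
    "window_wppa",
    "scan_windows",
]


@dataclass
class Window:
    start_cm: float
    end_cm: float
    snp_ids: np.ndarray  # indices into the panel (positions array)


@dataclass
class WindowScan:
    """Per-window WPPA track over a panel."""

    windows: List[Window]
    positions_cm: np.ndarray
    freqs: np.ndarray
    sigma2_gw_samples: np.ndarray   # (n_windows, n_samples)
    e_sigma2_gw: np.ndarray         # (n_windows,)
    wppa: np.ndarray                # (n_windows,), NaN where undefined
    window_vd_samples: Optional[np.ndarray] = None
    window_size_cm: float = 0.0
    model: str = ""

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def qw_samples(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.sigma2_gw_samples / self.e_sigma2_gw[:, None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anchor_snp": np.arange(self.n_windows),
                "start_cm": [w.start_cm for w in self.windows],
                "end_cm": [w.end_cm for w in self.windows],
                "n_snps": [len(w.snp_ids) for w in self.windows],
                "wppa": self.wppa,
                "mean_sigma2_gw": self.sigma2_gw_samples.mean(axis=1),
                "mean_window_vd": (
                    self.window_vd_samples.mean(axis=1)
                    if self.window_vd_samples is not None
                    else np.zeros(self.n_windows)
                ),
                "e_sigma2_gw": self.e_sigma2_gw,
            }
        )


def sliding_windows(
    positions_cm: np.ndarray, size_cm: float, map_end_cm: float = 100.0
) -> List[Window]:
    """One half-open window [pos_i, pos_i + size) anchored at each SNP,
    truncated at the map end."""
    pos = np.asarray(positions_cm, dtype=np.float64)
    if len(pos) == 0:
        raise ValueError("empty panel")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    windows = []
    for i, start in enumerate(pos):
        end = min(start + size_cm, map_end_cm)
        hi = int(np.searchsorted(pos, start + size_cm, side="left"))
        windows.append(Window(start, end, np.arange(i, hi, dtype=np.int64)))
    return windows


def window_genomic_variance(
    a: np.ndarray, d: np.ndarray, freqs: np.ndarray, window: Window
) -> float:
    """sum_{j in w} H_j alpha_j^2 + H_j^2 d_j^2 for one effect sample."""
    j = window.snp_ids
    if len(j) and (j.max() >= len(a)):
        raise IndexError("window references SNPs outside the panel")
    p = freqs[j]
    H = 2.0 * p * (1.0 - p)
    alpha = a[j] + (1.0 - 2.0 * p) * d[j]
    return float(np.sum(H * alpha**2 + H**2 * d[j] ** 2))


def expected_window_variance(
    freqs: np.ndarray, window: Window, v_a_in: float, v_d_in: float
) -> float:
    """Equal-distribution expectation of the window genomic variance."""
    p = np.asarray(freqs, dtype=np.float64)
    H = 2.0 * p * (1.0 - p)
    sum_h = H.sum()
    sum_h2 = (H**2).sum()
    if sum_h <= 0:
        raise ValueError("panel is entirely monomorphic")
    e_alpha2 = v_a_in / sum_h
    e_d2 = v_d_in / sum_h2 if sum_h2 > 0 else 0.0
    j = window.snp_ids
    return float(np.sum(H[j] * e_alpha2 + H[j] ** 2 * e_d2))


def window_wppa(sigma2_samples: np.ndarray, expectation: float) -> float:
    """Fraction of samples with q_w strictly above 1 (ties do not count);
    NaN if the expectation is zero while samples are not."""
    s = np.asarray(sigma2_samples, dtype=np.float64)
    if len(s) == 0:
        raise ValueError("need at least one stored sample")
    if expectation <= 0:
        return 0.0 if np.all(s == 0) else float("nan")
    return float(np.mean(s > expectation))


def scan_windows(
    samples: PosteriorSamples,
    positions_cm: np.ndarray,
    v_a_in: float,
    v_d_in: float,
    window_size_cm: float,
    freqs: Optional[np.ndarray] = None,
    map_end_cm: float = 100.0,
) -> WindowScan:
    """Full WPPA track for one posterior-sample set.

    ``freqs`` defaults to the allele frequencies recorded with the samples.
    v_a_in / v_d_in must be the same inputs given to the sampler so that
    q_w is the ratio the model was calibrated for.
    """
    p = samples.freqs if freqs is None else np.asarray(freqs, float)
    positions_cm = np.asarray(positions_cm, dtype=np.float64)
    if len(positions_cm) != samples.a_s.shape[1] or len(p) != len(positions_cm):
        raise ValueError("positions/freqs do not match the sampled panel")
    windows = sliding_windows(positions_cm, window_size_cm, map_end_cm)
    a_s = samples.a_s
    d_s = samples.dominance()
    H = 2.0 * p * (1.0 - p)
    alpha_s = a_s + (1.0 - 2.0 * p)[None, :] * d_s
    per_snp = H[None, :] * alpha_s**2 + (H**2)[None, :] * d_s**2
    per_snp_vd = (H**2)[None, :] * d_s**2
    # windows are contiguous index ranges: cumulative sums give O(1) windows
    csum = np.concatenate(
        [np.zeros((per_snp.shape[0], 1)), np.cumsum(per_snp, axis=1)], axis=1
    )
    csum_vd = np.concatenate(
        [np.zeros((per_snp.shape[0], 1)), np.cumsum(per_snp_vd, axis=1)],
        axis=1,
    )
    n_w = len(windows)
    sig = np.empty((n_w, per_snp.shape[0]))
    sig_vd = np.empty_like(sig)
    e_sig = np.empty(n_w)
    for i, w in enumerate(windows):
        lo = w.snp_ids[0] if len(w.snp_ids) else 0
        hi = w.snp_ids[-1] + 1 if len(w.snp_ids) else 0
        sig[i] = csum[:, hi] - csum[:, lo]
        sig_vd[i] = csum_vd[:, hi] - csum_vd[:, lo]
        e_sig[i] = expected_window_variance(p, w, v_a_in, v_d_in)
    wppa = np.array([window_wppa(sig[i], e_sig[i]) for i in range(n_w)])
    return WindowScan(
        windows=windows,
        positions_cm=positions_cm,
        freqs=p,
        sigma2_gw_samples=sig,
        e_sigma2_gw=e_sig,
        wppa=wppa,
        window_vd_samples=sig_vd if samples.d_s is not None else None,
        window_size_cm=window_size_cm,
        model=samples.model,
    )
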