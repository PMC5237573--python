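"""Power, L-power and mapping precision of WPPA scans across replicates.

A causative locus is *detectable* when its genetic variance contribution
v_j = H_j alpha_j^2 + H_j^2 d_j^2 exceeds the equal-distribution
expectation of a window of the configured size around it (otherwise q_w
cannot be expected to exceed 1 and the locus would deflate the power
denominator artificially).  It is *large* when it explains more than 2.5%
of the trait's genetic variance.

A locus is *mapped* at a WPPA threshold when at least one window with
WPPA above the threshold intersects the 1-cM region around it.  Mapping
precision is the genetic extent of the contiguous cluster of significant
windows nearest the locus; its lower bound is the window size.

Power is the per-trait ratio mapped/detectable, averaged over traits;
L-power restricts both counts to large loci.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import bayes_mcmc, popsim, trait_model, wppa as wppa_mod

__all__ = [
    "MappingResult",
    "DENSITY_PRESETS",
    "derive_seed",
    "detectable_qtl",
    "map_qtl",
    "power_tables",
    "ExperimentConfig",
    "run_experiment",
]

#: density label -> (panel size or None for all, MAF cutoff, keep causal
#: sites, density exponent t of the pLD schedule)
DENSITY_PRESETS: Dict[str, Tuple[Optional[int], float, bool, float]] = {
    "0.5k": (500, 0.03, False, 1.0),
    "1k": (1000, 0.03, False, 2.0),
    "2k": (2000, 0.03, False, 3.0),
    "7k": (None, 0.01, True, 4.8),
}


def derive_seed(master: int, *parts) -> int:
    """Deterministic sub-seed from a master seed and stage labels."""
    key = ":".join([str(master), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class MappingResult:
    qtl_id: int
    position_cm: float
    variance: float
    detectable: bool
    large: bool
    mapped_at: Dict[float, bool]
    precision_cm: Dict[float, float]  # NaN when unmapped


def detectable_qtl(
    qtl: trait_model.QTLSet,
    panel_positions_cm: np.ndarray,
    panel_freqs: np.ndarray,
    v_a_in: float,
    v_d_in: float,
    window_size_cm: float,
    map_end_cm: float = 100.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """(detectable, large) flags per QTL.

    The detection bar for a QTL is the mean equal-distribution expectation
    of the sliding windows (of the configured size) that contain its
    position; the nearest window is used if none contains it.
    """
    windows = wppa_mod.sliding_windows(
        panel_positions_cm, window_size_cm, map_end_cm
    )
    e_sig = np.array(
        [
            wppa_mod.expected_window_variance(panel_freqs, w, v_a_in, v_d_in)
            for w in windows
        ]
    )
    starts = np.array([w.start_cm for w in windows])
    v_j = qtl.variance_contributions()
    detect = np.zeros(qtl.n_qtl, dtype=bool)
    for i, pos in enumerate(qtl.positions_cm):
        inside = (starts <= pos) & (pos < starts + window_size_cm)
        if inside.any():
            bar = float(e_sig[inside].mean())
        else:
            bar = float(e_sig[np.argmin(np.abs(starts - pos))])
        detect[i] = v_j[i] > bar
    total = v_j.sum()
    large = v_j / total > 0.025 if total > 0 else np.zeros_like(detect)
    return detect, large


def _significant_clusters(
    scan: "wppa_mod.WindowScan", threshold: float
) -> List[Tuple[float, float]]:
    """Merged [start, end] intervals of windows with WPPA above threshold."""
    sig = np.flatnonzero(
        np.nan_to_num(scan.wppa, nan=0.0) > threshold
    )
    clusters: List[Tuple[float, float]] = []
    for i in sig:
        w = scan.windows[i]
        if clusters and w.start_cm <= clusters[-1][1]:
            clusters[-1] = (clusters[-1][0], max(clusters[-1][1], w.end_cm))
        else:
            clusters.append((w.start_cm, w.end_cm))
    return clusters


def map_qtl(
    scan: "wppa_mod.WindowScan",
    qtl: trait_model.QTLSet,
    thresholds: Sequence[float] = (0.85, 0.95, 0.99),
    flank_cm: float = 1.0,
    detect: Optional[np.ndarray] = None,
    large: Optional[np.ndarray] = None,
) -> List[MappingResult]:
    """Per-QTL mapping decisions and precisions for each WPPA threshold."""
    v_j = qtl.variance_contributions()
    if detect is None:
        detect = np.ones(qtl.n_qtl, dtype=bool)
    if large is None:
        large = np.ones(qtl.n_qtl, dtype=bool)
    results = []
    clusters_by_thr = {
        thr: _significant_clusters(scan, thr) for thr in thresholds
    }
    for i in range(qtl.n_qtl):
        pos = float(qtl.positions_cm[i])
        mapped_at: Dict[float, bool] = {}
        precision: Dict[float, float] = {}
        for thr in thresholds:
            lo, hi = pos - flank_cm, pos + flank_cm
            best = None
            best_dist = np.inf
            for cs, ce in clusters_by_thr[thr]:
                if ce >= lo and cs <= hi:
                    dist = abs((cs + ce) / 2.0 - pos)
                    if dist < best_dist:
                        best, best_dist = (cs, ce), dist
            mapped_at[thr] = best is not None
            precision[thr] = (best[1] - best[0]) if best else float("nan")
        results.append(
            MappingResult(
                qtl_id=int(qtl.site_ids[i]),
                position_cm=pos,
                variance=float(v_j[i]),
                detectable=bool(detect[i]),
                large=bool(large[i]),
                mapped_at=mapped_at,
                precision_cm=precision,
            )
        )
    return results


def power_tables(
    per_trait_results: Iterable[List[MappingResult]],
    thresholds: Sequence[float] = (0.85, 0.95, 0.99),
) -> pd.DataFrame:
    """Average power / L-power / precision over traits.

    Traits with no detectable QTL are excluded from the power average (and
    traits with no large detectable QTL from the L-power average).
    """
    rows = []
    for thr in thresholds:
        powers, lpowers, precisions = [], [], []
        for res in per_trait_results:
            det = [r for r in res if r.detectable]
            if det:
                powers.append(
                    sum(r.mapped_at[thr] for r in det) / len(det)
                )
            big = [r for r in det if r.large]
            if big:
                lpowers.append(
                    sum(r.mapped_at[thr] for r in big) / len(big)
                )
            prec = [
                r.precision_cm[thr]
                for r in res
                if r.detectable and r.mapped_at[thr]
            ]
            if prec:
                precisions.append(float(np.mean(prec)))
        rows.append(
            {
                "wppa": thr,
                "power": float(np.mean(powers)) if powers else float("nan"),
                "power_sd": float(np.std(powers, ddof=1))
                if len(powers) > 1 else float("nan"),
                "l_power": float(np.mean(lpowers))
                if lpowers else float("nan"),
                "l_power_sd": float(np.std(lpowers, ddof=1))
                if len(lpowers) > 1 else float("nan"),
                "precision": float(np.mean(precisions))
                if precisions else float("nan"),
                "precision_sd": float(np.std(precisions, ddof=1))
                if len(precisions) > 1 else float("nan"),
                "n_traits": len(powers),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ExperimentConfig:
    """Grid specification for a simulation study."""

    n_populations: int = 1
    n_traits: int = 5                       # per population
    densities: Sequence[str] = ("2k",)
    window_sizes: Sequence[float] = (0.25, 0.5, 1.0)
    thresholds: Sequence[float] = (0.85, 0.95, 0.99)
    models: Sequence[str] = ("bayesc", "bayesd")
    demography: popsim.DemographyConfig = field(
        default_factory=popsim.DemographyConfig
    )
    n_qtl: int = 15
    qtl_maf_min: float = 0.05
    qtl_min_distance_cm: float = 2.0
    h2: float = 0.3
    mcmc: bayes_mcmc.MCMCConfig = field(default_factory=bayes_mcmc.MCMCConfig)
    epsilon: float = 0.01
    df_t: float = 2.5
    seed: int = 0


def _fit_models(
    pop: popsim.Population,
    trait: trait_model.TraitRealization,
    density: str,
    models: Sequence[str],
    cfg: ExperimentConfig,
    fit_seed: int,
) -> Dict[str, Tuple[bayes_mcmc.PosteriorSamples, np.ndarray]]:
    count, maf_min, keep, t_exp = DENSITY_PRESETS[density]
    panel = popsim.select_marker_panel(
        pop, count, maf_min,
        causal_ids=trait.qtl.site_ids, keep_causals=keep,
        density_label=density,
    )
    X = pop.genotypes(panel.snp_indices)
    pld = bayes_mcmc.pld_schedule(t_exp)
    out = {}
    for model in models:
        inputs = bayes_mcmc.ModelInputs(
            y=trait.y, X=X,
            v_a_in=trait.v_a, v_d_in=trait.v_d, v_e_in=trait.v_e,
            inb_dep_in=trait.inb_dep,
        )
        prior = bayes_mcmc.calibrate_priors(
            inputs, pld, cfg.epsilon, cfg.df_t,
            model="D" if model == "bayesd" else "C",
        )
        mcmc = bayes_mcmc.MCMCConfig(
            n_cycles=cfg.mcmc.n_cycles, burn_in=cfg.mcmc.burn_in,
            thin=cfg.mcmc.thin,
            seed=derive_seed(fit_seed, model),
        )
        runner = (
            bayes_mcmc.run_bayesd if model == "bayesd"
            else bayes_mcmc.run_bayesc
        )
        out[model] = (
            runner(inputs, prior, mcmc),
            pop.positions_cm[panel.snp_indices],
        )
    return out


def run_experiment(cfg: ExperimentConfig, log=None) -> pd.DataFrame:
    """Simulate, fit, scan and evaluate the full grid.

    Returns a long-format table with one row per (density, window size,
    WPPA threshold, model).  Each cell is independently seeded from the
    master seed, so identical configs give identical tables.  Per-cell
    failures are logged and skipped rather than aborting the grid.
    """
    collected: Dict[Tuple[str, float, str], List[List[MappingResult]]] = {}
    for ipop in range(cfg.n_populations):
        demog = popsim.DemographyConfig(
            **{
                **cfg.demography.__dict__,
                "seed": derive_seed(cfg.seed, "pop", ipop),
            }
        )
        pop = popsim.simulate_population(demog)
        for itrait in range(cfg.n_traits):
            rng = np.random.default_rng(
                derive_seed(cfg.seed, "trait", ipop, itrait)
            )
            trait = trait_model.simulate_trait(
                pop, cfg.n_qtl, cfg.qtl_maf_min,
                cfg.qtl_min_distance_cm, cfg.h2, rng,
            )
            for density in cfg.densities:
                try:
                    fits = _fit_models(
                        pop, trait, density, cfg.models, cfg,
                        derive_seed(cfg.seed, "fit", ipop, itrait, density),
                    )
                except Exception as exc:  # noqa: BLE001 - per-cell isolation
                    if log is not None:
                        log(f"cell pop={ipop} trait={itrait} "
                            f"density={density} failed: {exc!r}")
                    continue
                for model, (samples, positions) in fits.items():
                    for ws in cfg.window_sizes:
                        scan = wppa_mod.scan_windows(
                            samples, positions,
                            trait.v_a, trait.v_d, ws,
                        )
                        detect, large = detectable_qtl(
                            trait.qtl, positions, samples.freqs,
                            trait.v_a, trait.v_d, ws,
                        )
                        res = map_qtl(
                            scan, trait.qtl, cfg.thresholds,
                            detect=detect, large=large,
                        )
                        collected.setdefault(
                            (density, ws, model), []
                        ).append(res)
    frames = []
    for (density, ws, model), per_trait in collected.items():
        tab = power_tables(per_trait, cfg.thresholds)
        tab.insert(0, "model", model)
        tab.insert(0, "ws", ws)
        tab.insert(0, "density", density)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(
            columns=["density", "ws", "model", "wppa", "power", "power_sd",
                     "l_power", "l_power_sd", "precision", "precision_sd",
                     "n_traits"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["density", "ws", "model", "wppa"], ignore_index=True
    )
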