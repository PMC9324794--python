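"""Scripted simulation experiments: parameter sweeps over synthetic worlds.

Each sweep generates seeded synthetic multilayer networks over a parameter
grid, runs conserved-control-path detection, and returns a tidy
:class:`pandas.DataFrame` (one row per grid point and replicate) ready for
aggregation or plotting.  Failures in a single grid cell are logged and
recorded as NaN rows rather than aborting the whole sweep.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import run_copath
from .metrics import overlap_ratio
from .netmodel import MultilayerNetwork
from .synthetic import SyntheticSpec, add_weight_noise, cross_edges, generate_multilayer

__all__ = [
    "mean_cv",
    "sweep_layers",
    "sweep_noise",
    "sweep_node_diff",
    "sweep_density",
    "sweep_cross",
]

log = logging.getLogger(__name__)
_MAX_SEED = 2**31 - 1


def _replicate_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, _MAX_SEED, size=n)]


def mean_cv(spec: SyntheticSpec, n_reps: int = 10, seed: int = 0) -> float:
    """Mean CV over ``n_reps`` freshly seeded networks drawn from ``spec``."""
    values = []
    for s in _replicate_seeds(seed, n_reps):
        net = generate_multilayer(replace(spec, seed=s))
        values.append(run_copath(net).cv)
    return float(np.mean(values))


def _run_cell(spec: SyntheticSpec) -> float:
    return run_copath(generate_multilayer(spec)).cv


def sweep_layers(
    layer_values: Sequence[int] = tuple(range(2, 11)),
    p_common_values: Sequence[float] = (0.0, 0.5, 0.9),
    base_spec: SyntheticSpec = SyntheticSpec(),
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV as a function of the number of layers and common-edge proportion."""
    rows = []
    for pc in p_common_values:
        for L in layer_values:
            for rep, s in enumerate(_replicate_seeds(seed, n_reps)):
                spec = replace(base_spec, n_layers=L, p_common=pc, seed=s)
                try:
                    value = _run_cell(spec)
                except Exception:  # keep the sweep alive, record the gap
                    log.exception("sweep cell failed: L=%s p_common=%s rep=%s",
                                  L, pc, rep)
                    value = float("nan")
                rows.append({"n_layers": L, "p_common": pc, "replicate": rep,
                             "seed": s, "cv": value})
    return pd.DataFrame(rows)


def sweep_noise(
    sigmas: Sequence[float] = (1.0, 3.0, 5.0, 25.0),
    base_spec: SyntheticSpec = SyntheticSpec(n_layers=5, p_common=0.9),
    n_reps: int = 10,
    seed: int = 0,
    use_weight_tiebreak: bool = False,
) -> pd.DataFrame:
    """CV and CCP edge overlap before/after Gaussian weight noise.

    For each replicate the same network is solved clean and with noisy
    weights; ``overlap`` is the median over layers of the Jaccard overlap
    of each layer's control-path edges before vs after.  With the default
    objective weights are ignored, so ``cv_noisy == cv_clean`` exactly;
    with ``use_weight_tiebreak`` noise may flip ties between equally
    conserved matchings.
    """
    rows = []
    for rep, s in enumerate(_replicate_seeds(seed, n_reps)):
        spec = replace(base_spec, seed=s)
        net = generate_multilayer(spec)
        clean = run_copath(net, use_weight_tiebreak=use_weight_tiebreak)
        for sig_i, sigma in enumerate(sigmas):
            noisy_layers = [
                add_weight_noise(l, sigma, seed=(s + 7919 * (sig_i + 1)) % _MAX_SEED)
                for l in net.layers
            ]
            noisy = run_copath(MultilayerNetwork(layers=noisy_layers),
                               use_weight_tiebreak=use_weight_tiebreak)
            overlaps = [
                overlap_ratio(clean.per_layer_paths[lid], noisy.per_layer_paths[lid])
                for lid in net.layer_ids
            ]
            rows.append({
                "sigma": sigma, "replicate": rep, "seed": s,
                "cv_clean": clean.cv, "cv_noisy": noisy.cv,
                "overlap": float(np.median(overlaps)),
            })
    return pd.DataFrame(rows)


def sweep_node_diff(
    ratios: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    base_spec: SyntheticSpec = SyntheticSpec(n_layers=5, p_common=0.9),
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV as a function of the ratio of difference nodes between layers."""
    rows = []
    for ratio in ratios:
        for rep, s in enumerate(_replicate_seeds(seed, n_reps)):
            spec = replace(base_spec, node_diff_ratio=ratio, seed=s)
            try:
                value = _run_cell(spec)
            except Exception:
                log.exception("sweep cell failed: ratio=%s rep=%s", ratio, rep)
                value = float("nan")
            rows.append({"node_diff_ratio": ratio, "replicate": rep, "seed": s,
                         "cv": value})
    return pd.DataFrame(rows)


def sweep_density(
    mean_degrees: Sequence[float] = (1.0, 2.0, 3.0, 5.0, 8.0),
    base_spec: SyntheticSpec = SyntheticSpec(n_layers=5, p_common=0.5),
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV as a function of network density (parameterized by mean degree).

    ``n_edges`` is set to ``mean_degree * n_nodes / 2`` per layer (mean
    total degree counts each directed edge at both endpoints); the derived
    density m / (n (n-1)) is reported alongside.
    """
    rows = []
    n = base_spec.n_nodes
    for kbar in mean_degrees:
        m = int(round(kbar * n / 2))
        for rep, s in enumerate(_replicate_seeds(seed, n_reps)):
            spec = replace(base_spec, n_edges=m, seed=s)
            try:
                value = _run_cell(spec)
            except Exception:
                log.exception("sweep cell failed: k=%s rep=%s", kbar, rep)
                value = float("nan")
            rows.append({
                "mean_degree": kbar, "n_edges": m,
                "density": m / (n * (n - 1)), "replicate": rep, "seed": s,
                "cv": value,
            })
    return pd.DataFrame(rows)


def sweep_cross(
    fractions: Sequence[float] = (0.0, 0.02, 0.04, 0.08),
    base_spec: SyntheticSpec = SyntheticSpec(n_layers=5, p_common=0.9),
    n_reps: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """CV/CV0 of a multilayer network whose layers are perturbed by
    degree-preserving edge crossings, versus the fraction of crossed edges.

    CV0 is the unperturbed network's CV; at fraction 0 the ratio is 1 by
    construction.  Each swap crosses two edges, so a fraction f of crossed
    edges corresponds to ``f * n_edges / 2`` swaps per layer.
    """
    rows = []
    for rep, s in enumerate(_replicate_seeds(seed, n_reps)):
        spec = replace(base_spec, seed=s)
        net = generate_multilayer(spec)
        cv0 = run_copath(net).cv
        for f_i, f in enumerate(fractions):
            n_swaps = int(round(f * base_spec.n_edges / 2))
            if n_swaps == 0:
                value = cv0
            else:
                perturbed = MultilayerNetwork(layers=[
                    cross_edges(l, n_swaps,
                                seed=(s + 104729 * (f_i + 1) + li) % _MAX_SEED)
                    for li, l in enumerate(net.layers)
                ])
                value = run_copath(perturbed).cv
            rows.append({"crossed_fraction": f, "n_swaps": n_swaps,
                         "replicate": rep, "seed": s, "cv": value,
                         "cv0": cv0, "cv_ratio": value / cv0 if cv0 else float("nan")})
    return pd.DataFrame(rows)
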