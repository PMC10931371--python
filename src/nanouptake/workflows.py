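"""End-to-end study workflows used by the validation scripts and tests.

These compose the synthetic generators with the full analysis chains and
measure recovery of planted ground truth — e.g. whether the unmixed
endmember assigned to polystyrene still carries the printed fingerprint
band positions after preprocessing of a noisy cell-scan cube.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .raman import (
    AbundanceStack,
    EndmemberSet,
    nfindr_extract,
    nnls_abundances,
    peak_positions,
    preprocess,
)
from .synthetic import RamanFixture, make_raman_fixture

__all__ = [
    "identify_endmembers_by_layout",
    "band_recovery_study",
    "unmix_noiseless_fixture",
]

_COMPONENTS = ("water", "lipid", "polystyrene")


def identify_endmembers_by_layout(
    fixture: RamanFixture, abundances: AbundanceStack
) -> dict[str, int]:
    """Match endmembers to planted components by abundance overlap.

    For every (component, endmember) pair the score is the mean abundance
    inside the planted region minus the mean outside; the optimal
    one-to-one assignment over all pairs is returned as a mapping
    component label -> endmember index.
    """
    k = abundances.k
    scores = np.zeros((len(_COMPONENTS), k))
    for ci, comp in enumerate(_COMPONENTS):
        mask = fixture.layout_mask(comp)
        for j in range(k):
            amap = abundances.maps[j]
            scores[ci, j] = amap[mask].mean() - amap[~mask].mean()
    rows, cols = linear_sum_assignment(-scores)
    return {_COMPONENTS[r]: int(c) for r, c in zip(rows, cols)}


def band_recovery_study(
    seed: int,
    k: int = 3,
    n_restarts: int = 5,
    **fixture_kwargs,
) -> dict[str, float]:
    """Full-pipeline band-position recovery on one synthetic cell scan.

    Generates the default noisy cube (degree-3 baseline, peak SNR 20,
    0.5% spike pixels), runs despike/SNIP/silent-cut/normalize, N-FINDR
    with ``k`` endmembers and NNLS abundances, identifies the endmembers
    against the planted layout, and reports:

    * ``ps_max_below_1800``: wavenumber of the polystyrene endmember's
      most intense band below 1800 cm^-1,
    * ``ps_lowest_peak``: its lowest-wavenumber peak at >= 10% prominence,
    * ``lipid_max_1500_1800`` and ``water_max_1500_1800``: the strongest
      band of the lipid / water endmember within 1500-1800 cm^-1.
    """
    fx = make_raman_fixture(seed=seed, **fixture_kwargs)
    pre, degenerate = preprocess(fx.cube)
    ems = nfindr_extract(
        pre, k=k, n_restarts=n_restarts, seed=seed,
        degenerate_mask=degenerate,
    )
    ab = nnls_abundances(pre, ems)
    who = identify_endmembers_by_layout(fx, ab)
    axis = pre.axis

    def window_max(spec: np.ndarray, lo: float, hi: float) -> float:
        sel = (axis >= lo) & (axis <= hi)
        return float(axis[sel][np.argmax(spec[sel])])

    ps = ems.spectra[who["polystyrene"]]
    lipid = ems.spectra[who["lipid"]]
    water = ems.spectra[who["water"]]
    peaks = peak_positions(axis, ps, prominence_fraction=0.1)
    return {
        "ps_max_below_1800": window_max(ps, axis[0], 1800.0),
        "ps_lowest_peak": float(peaks.min()) if peaks.size else float("nan"),
        "lipid_max_1500_1800": window_max(lipid, 1500.0, 1800.0),
        "water_max_1500_1800": window_max(water, 1500.0, 1800.0),
    }


def unmix_noiseless_fixture(
    seed: int, grid: tuple[int, int] = (36, 36)
) -> tuple[RamanFixture, EndmemberSet, AbundanceStack, dict[str, int]]:
    """Noiseless pure-pixel fixture unmixed without preprocessing.

    The grid is roomy enough that all planted droplets and clusters fit,
    so every component retains pure pixels.
    """
    fx = make_raman_fixture(
        grid=grid, n_z=1, snr=np.inf, baseline_degree=0,
        spike_fraction=0.0, n_lipid_droplets=3, n_ps_clusters=2, seed=seed,
    )
    ems = nfindr_extract(fx.cube, k=3, n_restarts=5, seed=seed)
    ab = nnls_abundances(fx.cube, ems)
    return fx, ems, ab, identify_endmembers_by_layout(fx, ab)
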