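"""Synthetic confocal and Raman scenes with known ground truth.

Every downstream stage of the package is exercised against fixtures built
here: Raman hyperspectral cubes mixing water, lipid and polystyrene
components from the band library, and confocal fluorescence z-stacks with
stained nuclei, actin-delimited cell bodies and sub-resolution bead puncta
whose density scales with the nominal exposure concentration.  All
generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .bands import ComponentLibrary, default_axis, default_library
from .raman import AbundanceStack, EndmemberSet, RamanCube

__all__ = [
    "RamanFixture",
    "ConfocalFixture",
    "DoseRecord",
    "DoseResponseSet",
    "COMPONENT_SCALES",
    "PAPER_CONCENTRATIONS",
    "make_raman_fixture",
    "make_confocal_fixture",
    "make_dose_response_set",
]

#: Nominal exposure concentrations of the uptake study, in ug/cm^2.
PAPER_CONCENTRATIONS: tuple[float, ...] = (7.81, 15.63, 31.25)

#: Relative emission scale per component. Polystyrene beads are strong
#: Raman scatterers; water gives a weak broad signal but fills the bulk.
COMPONENT_SCALES: dict[str, float] = {
    "water": 1.0,
    "lipid": 1.2,
    "polystyrene": 1.6,
}

_COMPONENT_ORDER = ("water", "lipid", "polystyrene")


# --------------------------------------------------------------------------
# Raman fixtures


@dataclass
class RamanFixture:
    """A synthetic Raman cube plus the ground truth it was built from."""

    cube: RamanCube
    truth_endmembers: EndmemberSet
    truth_abundance: AbundanceStack
    layout: np.ndarray  # (n_z, n_y, n_x) labels: 0 water, 1 lipid, 2 PS
    seed: int

    def layout_mask(self, label: str) -> np.ndarray:
        """Boolean mask of the planted region for a component label."""
        code = {_c: i for i, _c in enumerate(_COMPONENT_ORDER)}[label]
        return self.layout == code


def _place_blobs(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_blobs: int,
    radius_range: tuple[float, float],
    occupied: np.ndarray,
    clearance: int = 3,
) -> np.ndarray:
    """Plant round blobs avoiding ``occupied`` pixels (plus clearance)."""
    ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:ny, 0:nx]
    r_cap = (min(ny, nx) - 2.5) / 2.0  # largest blob the grid can hold
    placed = 0
    for _ in range(200 * max(n_blobs, 1)):
        if placed >= n_blobs:
            break
        r = min(rng.uniform(*radius_range), r_cap)
        if r < 1.0:
            break
        cy = rng.uniform(r + 1, ny - r - 1)
        cx = rng.uniform(r + 1, nx - r - 1)
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        halo = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r + clearance) ** 2
        if not (halo & occupied).any():
            mask |= blob
            occupied |= halo
            placed += 1
    return mask


def make_raman_fixture(
    grid: tuple[int, int] = (50, 50),
    step_um: float = 0.5,
    n_z: int = 3,
    z_step_um: float = 1.5,
    axis: np.ndarray | None = None,
    library: ComponentLibrary | None = None,
    n_lipid_droplets: int = 4,
    n_ps_clusters: int = 3,
    baseline_degree: int = 3,
    baseline_amplitude: float = 0.3,
    snr: float = 20.0,
    spike_fraction: float = 0.005,
    spike_gain: float = 25.0,
    seed: int = 0,
) -> RamanFixture:
    """Generate a cell-scan-like Raman cube with planted ground truth.

    The default geometry emulates a single-cell scan: a 25 um x 25 um field
    sampled every 0.5 um (50 x 50 pixels) in three z-planes 1.5 um apart.
    The scene is bulk water with round lipid droplets and polystyrene
    clusters; component regions mix only at their one-pixel boundary, so
    each component retains pure pixels.  Per pixel,

        spectrum = sum_c abundance_c * scale_c * reference_c(axis)
                   + polynomial baseline + shot noise (+ cosmic spikes).

    Parameters
    ----------
    baseline_degree : int
        Degree of the per-pixel polynomial baseline; 0 disables the
        baseline entirely (noiseless-limit contract).
    baseline_amplitude : float
        Baseline scale as a fraction of the clean-signal peak.
    snr : float
        Peak signal-to-noise ratio of the Poisson shot noise;
        ``numpy.inf`` disables noise (and the 1%-of-peak read noise).
    spike_fraction : float
        Fraction of pixels receiving one single-channel cosmic spike of
        ``spike_gain`` times the pixel's peak signal; must be <= 0.05.

    Raises
    ------
    ValueError
        For non-positive snr or a spike fraction outside [0, 0.05].
    """
    if not snr > 0:
        raise ValueError("snr must be positive (use numpy.inf for noiseless)")
    if not 0 <= spike_fraction <= 0.05:
        raise ValueError("spike_fraction must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    axis = default_axis() if axis is None else np.asarray(axis, dtype=float)
    library = library or default_library()
    ny, nx = grid
    if ny < 4 or nx < 4:
        raise ValueError("grid too small for a scene layout")

    refs = np.stack(
        [
            COMPONENT_SCALES[c] * library.reference_spectrum(c, axis)
            for c in _COMPONENT_ORDER
        ]
    )  # (3, n_channels)

    layout = np.zeros((n_z, ny, nx), dtype=np.int8)
    abund = np.zeros((3, n_z, ny, nx), dtype=float)
    for z in range(n_z):
        occupied = np.zeros((ny, nx), dtype=bool)
        lipid = _place_blobs(
            rng, (ny, nx), n_lipid_droplets, (2.5, 4.5), occupied
        )
        ps = _place_blobs(rng, (ny, nx), n_ps_clusters, (1.5, 3.5), occupied)
        layout[z][lipid] = 1
        layout[z][ps] = 2
        # box-filter mixing: interiors stay exactly pure, edges mix.
        # integer neighborhood sums keep interior abundances exactly 1.0
        kernel = np.ones((3, 3))
        a_lip = ndi.correlate(lipid.astype(float), kernel, mode="constant") / 9.0
        a_ps = ndi.correlate(ps.astype(float), kernel, mode="constant") / 9.0
        a_wat = np.clip(1.0 - a_lip - a_ps, 0.0, 1.0)
        abund[0, z], abund[1, z], abund[2, z] = a_wat, a_lip, a_ps

    clean = np.tensordot(abund, refs, axes=([0], [0]))  # (z, y, x, n)
    peak = float(clean.max())

    intensities = clean.copy()
    if baseline_degree > 0 and baseline_amplitude > 0:
        t = np.linspace(0.0, 1.0, axis.size)
        powers = np.stack([t**d for d in range(baseline_degree + 1)])
        coeffs = np.concatenate(
            [
                rng.uniform(0.3, 1.0, size=(n_z, ny, nx, 1)),
                rng.uniform(-0.4, 0.4, size=(n_z, ny, nx, baseline_degree)),
            ],
            axis=-1,
        )
        baseline = np.clip(np.tensordot(coeffs, powers, axes=([3], [0])), 0, None)
        intensities = intensities + baseline_amplitude * peak * baseline

    if np.isfinite(snr):
        gain = snr**2 / peak  # Poisson gain: sd at the peak = peak / snr
        intensities = rng.poisson(np.clip(intensities, 0, None) * gain) / gain
        intensities = intensities + rng.normal(
            0.0, 0.01 * peak, size=intensities.shape
        )

    n_spiked = int(round(spike_fraction * n_z * ny * nx))
    if n_spiked:
        flat = intensities.reshape(-1, axis.size)
        pix = rng.choice(flat.shape[0], size=n_spiked, replace=False)
        chans = rng.integers(0, axis.size, size=n_spiked)
        for p, c in zip(pix, chans):
            local = max(flat[p].max(), 1e-3 * peak)
            flat[p, c] += spike_gain * local
        intensities = flat.reshape(intensities.shape)

    cube = RamanCube(
        axis=axis, intensities=intensities, step_um=step_um, z_step_um=z_step_um
    )
    truth_em = EndmemberSet(
        axis=axis, spectra=refs, labels=list(_COMPONENT_ORDER)
    )
    truth_ab = AbundanceStack(
        maps=abund, residual=np.zeros((n_z, ny, nx))
    )
    return RamanFixture(
        cube=cube,
        truth_endmembers=truth_em,
        truth_abundance=truth_ab,
        layout=layout,
        seed=seed,
    )


# --------------------------------------------------------------------------
# confocal fixtures


@dataclass
class ConfocalFixture:
    """A synthetic confocal z-stack plus the planted ground truth."""

    stack: "ConfocalStack"  # noqa: F821 - imported lazily to avoid a cycle
    truth_nuclei_count: int
    truth_nuclei_labels: np.ndarray  # (ny, nx) int labels
    truth_bead_mask: np.ndarray  # (ny, nx) bool, projected, pre-noise
    truth_cell_mask: np.ndarray  # (ny, nx) bool, union of cell bodies
    nominal_concentration: float
    exposure_time_h: float
    seed: int


def _draw_ellipse(
    shape: tuple[int, int],
    cy: float,
    cx: float,
    a: float,
    b: float,
    angle: float,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    co, si = np.cos(angle), np.sin(angle)
    u = (xx - cx) * co + (yy - cy) * si
    v = -(xx - cx) * si + (yy - cy) * co
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_confocal_fixture(
    image_shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.684,
    n_z: int = 5,
    z_step_um: float = 1.0,
    n_cells: int = 20,
    cell_line: str = "THP-1",
    concentration: float = 0.0,
    exposure_time_h: float = 24.0,
    bead_rate: float = 0.2,
    nucleus_area_range_um2: tuple[float, float] = (45.0, 110.0),
    cell_radius_range_px: tuple[float, float] = (16.0, 22.0),
    nucleus_intensity: float = 200.0,
    bead_amplitude: float = 180.0,
    bead_truth_level: float = 50.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
    n_debris: int = 0,
    debris_area_um2: float = 5.0,
    outside_bead_fraction: float = 0.0,
    seed: int = 0,
) -> ConfocalFixture:
    """Render a multi-channel confocal z-stack with planted cells and beads.

    The default field of view is 512 x 512 px at 0.684 um/px (about
    350 um x 350 um) with z-planes 1 um apart.  Cells are disks with an
    elliptical nucleus (DAPI channel), an actin body with a bright cortical
    rim (IF555 channel), a textured brightfield appearance, and
    sub-resolution bead puncta (sigma ~ 1 px Gaussians) planted uniformly
    inside cell bodies.  The expected bead count is
    ``Poisson(bead_rate * concentration * n_cells)``.

    ``n_debris`` bright sub-threshold specks (area ``debris_area_um2``)
    can be added to the nuclear channel to exercise the size filter, and
    ``outside_bead_fraction`` plants additional beads outside every cell
    body to exercise the cell-mask exclusion rule; neither enters the
    ground-truth bead mask or nuclei labels.

    Returns a :class:`ConfocalFixture` whose ``truth_bead_mask`` is the
    noise-free maximum projection of the planted puncta thresholded at
    ``bead_truth_level``.
    """
    from .fluor import ConfocalStack  # local import: fluor imports nothing here

    if image_shape[0] <= 0 or image_shape[1] <= 0:
        raise ValueError("image size must be positive")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")

    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    px_area = pixel_size_um**2

    # --- place cells with generous spacing
    radii = rng.uniform(*cell_radius_range_px, size=n_cells)
    centers: list[tuple[float, float]] = []
    for i in range(n_cells):
        r = radii[i]
        for _ in range(4000):
            cy = rng.uniform(r + 2, ny - r - 2)
            cx = rng.uniform(r + 2, nx - r - 2)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2
                >= (2.4 * max(r, radii[j])) ** 2
                for j, (oy, ox) in enumerate(centers)
            ):
                centers.append((cy, cx))
                break
        else:
            raise ValueError(
                f"could not place {n_cells} cells of this size in a "
                f"{ny}x{nx} field; reduce n_cells or the cell radius"
            )

    cell_mask = np.zeros((ny, nx), dtype=bool)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for (cy, cx), r in zip(centers, radii):
        cell_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2

    # --- nuclei
    labels = np.zeros((ny, nx), dtype=np.int32)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        area = rng.uniform(*nucleus_area_range_um2) / px_area  # px^2
        ratio = rng.uniform(1.0, 1.4)
        b = np.sqrt(area / (np.pi * ratio))
        a = b * ratio
        a = min(a, 0.85 * r)  # keep the nucleus inside the cell body
        ang = rng.uniform(0, np.pi)
        ell = _draw_ellipse((ny, nx), cy, cx, a, b, ang)
        labels[ell & (labels == 0)] = i

    # --- debris: bright specks below the size threshold (not in truth);
    # placed clear of nuclei and of each other so no merged object can
    # exceed the planted speck area
    debris = np.zeros((ny, nx), dtype=bool)
    r_d = np.sqrt(debris_area_um2 / px_area / np.pi)
    debris_centers: list[tuple[float, float]] = []
    for _ in range(n_debris):
        for _ in range(2000):
            cy = rng.uniform(r_d + 1, ny - r_d - 1)
            cx = rng.uniform(r_d + 1, nx - r_d - 1)
            near_debris = any(
                (cy - oy) ** 2 + (cx - ox) ** 2 < (8 * r_d) ** 2
                for oy, ox in debris_centers
            )
            near_nucleus = any(
                (cy - ncy) ** 2 + (cx - ncx) ** 2 < (3 * rc) ** 2
                for (ncy, ncx), rc in zip(centers, radii)
            )
            if not near_debris and not near_nucleus:
                debris_centers.append((cy, cx))
                debris |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_d**2
                break

    # --- beads
    n_beads = int(rng.poisson(bead_rate * concentration * n_cells))
    bead_planes = [np.zeros((ny, nx)) for _ in range(n_z)]
    cell_areas = radii**2
    if n_cells and n_beads:
        probs = cell_areas / cell_areas.sum()
        owners = rng.choice(n_cells, size=n_beads, p=probs)
        for c in owners:
            cy, cx = centers[c]
            r = radii[c]
            # 3 px margin keeps the punctum's above-threshold halo inside
            rr = max(r - 3.0, 0.0) * np.sqrt(rng.uniform(0, 1))
            th = rng.uniform(0, 2 * np.pi)
            by, bx = cy + rr * np.sin(th), cx + rr * np.cos(th)
            z = int(rng.integers(0, n_z))
            bead_planes[z] += bead_amplitude * np.exp(
                -((yy - by) ** 2 + (xx - bx) ** 2) / 2.0
            )
    bead_clean_proj = (
        np.max(np.stack(bead_planes), axis=0) if n_z else np.zeros((ny, nx))
    )
    # truth mask on the noise-free rendered channel (puncta + background)
    truth_bead_mask = bead_clean_proj + background >= bead_truth_level

    # beads outside every cell body (confounders; excluded from truth)
    n_outside = int(round(outside_bead_fraction * max(n_beads, 1)))
    outside = ndi.binary_dilation(cell_mask, iterations=4)
    for _ in range(n_outside):
        for _ in range(1000):
            by = rng.uniform(2, ny - 3)
            bx = rng.uniform(2, nx - 3)
            if not outside[int(by), int(bx)]:
                z = int(rng.integers(0, n_z))
                bead_planes[z] += bead_amplitude * np.exp(
                    -((yy - by) ** 2 + (xx - bx) ** 2) / 2.0
                )
                break

    # --- render channels (z, y, x)
    zc = (n_z - 1) / 2.0
    z_fade = 0.6 + 0.4 * np.exp(
        -(((np.arange(n_z) - zc) / max(n_z / 2.0, 1.0)) ** 2)
    )

    nuc_base = np.where(labels > 0, nucleus_intensity, 0.0)
    nuc_base = nuc_base + np.where(debris, nucleus_intensity, 0.0)
    nuc_base = ndi.gaussian_filter(nuc_base, 1.5)

    rim = cell_mask & ~ndi.binary_erosion(cell_mask, iterations=2)
    actin_base = ndi.gaussian_filter(
        np.where(cell_mask, 70.0, 0.0) + np.where(rim, 80.0, 0.0), 1.0
    )

    texture = ndi.gaussian_filter(rng.normal(0, 25.0, size=(ny, nx)), 1.0)
    bf_base = 120.0 + np.where(cell_mask, texture - 15.0, 0.0)
    bf_base = bf_base - np.where(rim, 40.0, 0.0)

    def _noisy(plane: np.ndarray) -> np.ndarray:
        return _quantize(
            plane + background + rng.normal(0, noise_sd, size=plane.shape)
        )

    channels = {
        "nuclei": np.stack([_noisy(nuc_base * f) for f in z_fade]),
        "actin": np.stack([_noisy(actin_base * f) for f in z_fade]),
        "beads": np.stack(
            [_noisy(bead_planes[z] * 1.0) for z in range(n_z)]
        ),
        "brightfield": np.stack(
            [_quantize(bf_base + rng.normal(0, noise_sd, size=(ny, nx)))
             for _ in range(n_z)]
        ),
    }

    stack = ConfocalStack(
        channels=channels, pixel_size_um=pixel_size_um, z_step_um=z_step_um
    )
    return ConfocalFixture(
        stack=stack,
        truth_nuclei_count=int(labels.max()),
        truth_nuclei_labels=labels,
        truth_bead_mask=truth_bead_mask,
        truth_cell_mask=cell_mask,
        nominal_concentration=concentration,
        exposure_time_h=exposure_time_h,
        seed=seed,
    )


# --------------------------------------------------------------------------
# dose-response sets


@dataclass(frozen=True)
class DoseRecord:
    cell_line: str
    concentration: float
    time_h: float
    replicate: int
    value: float


@dataclass
class DoseResponseSet:
    """Synthetic bead-pixels-per-cell values on a linear dose-response."""

    records: list[DoseRecord]
    truth_slope: float
    truth_intercept: float
    noise_sd: float

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        conc = np.array([r.concentration for r in self.records])
        vals = np.array([r.value for r in self.records])
        return conc, vals


def make_dose_response_set(
    truth_slope: float,
    truth_intercept: float,
    noise_sd: float,
    n_replicates: int,
    concentrations: tuple[float, ...] = PAPER_CONCENTRATIONS,
    cell_line: str = "THP-1",
    time_h: float = 24.0,
    seed: int = 0,
) -> DoseResponseSet:
    """Draw bead-px-per-cell values on a linear dose-response.

    values = intercept + slope * concentration + N(0, noise_sd^2),
    truncated at zero, with ``n_replicates`` values per concentration.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for conc in concentrations:
        mu = truth_intercept + truth_slope * conc
        vals = mu + rng.normal(0.0, noise_sd, size=n_replicates)
        for rep, v in enumerate(vals):
            records.append(
                DoseRecord(cell_line, conc, time_h, rep, max(float(v), 0.0))
            )
    return DoseResponseSet(
        records=records,
        truth_slope=truth_slope,
        truth_intercept=truth_intercept,
        noise_sd=noise_sd,
    )
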