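"""Synthetic fluorescence-microscopy scenes with exported ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: an epithelial monolayer of textured, moving nuclei (with dim
nucleoli) imaged in a nuclear-stain channel, a reporter channel whose
nuclear-to-cytoplasmic concentration ratio follows a per-cell program
(baseline plus localization-reset / ramp / stagnation events), an optional
spot channel carrying diffraction-limited nascent-transcription foci driven
by a two-state (telegraph) burst process, and two-pool nucleocytoplasmic
exchange recoveries for compartment-bleach experiments.

Everything is seeded: a fixed :class:`SceneConfig` seed yields byte-identical
arrays.  Ground truth (label maps, centroid paths, programmed N/C series,
burst state sequences, division records) is returned alongside each movie so
round-trip tests can score the pipeline against what was rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SceneConfig",
    "NCEvent",
    "NCProgram",
    "BurstProgram",
    "DivisionEvent",
    "Movie",
    "GroundTruth",
    "PlacementError",
    "nc_series",
    "generate_monolayer_movie",
    "generate_spot_movie",
    "simulate_compartment_bleach",
]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap."""


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics and noise model for a synthetic movie.

    Attributes
    ----------
    shape:
        ``(T, Z, Y, X)`` in pixels.  ``Z == 1`` produces a 2D movie.
    pixel_size_um:
        Lateral pixel size in micrometres (default matches a 63x confocal
        acquisition).
    frame_interval:
        Time between frames, in the caller's time unit (minutes for
        monolayer movies by convention).
    n_cells:
        Number of nuclei to place.
    semiaxes_px:
        ``(min, max)`` range of in-plane nucleus semi-axes, pixels.
    step_sigma_px:
        Per-frame random-walk displacement scale, pixels.
    nucleolus_fraction:
        Fraction of nuclear pixels occupied by the nucleolus, in ``[0, 1)``.
    nucleolus_dim:
        Multiplicative dimming of the nucleolus in both stain and reporter
        channels (the reporter is physically excluded from nucleoli).
    background:
        Fluorescence background added to every reporter/stain pixel.
    camera_offset:
        Constant camera offset added to every pixel of every channel.
    poisson_gain:
        Photons per intensity unit for shot noise; ``0`` disables shot noise.
    read_noise_sd:
        Additive Gaussian read noise standard deviation; ``0`` disables it.
    reporter_gain, cyto_level:
        Reporter channel renders cytoplasm at ``background + gain * cyto_level``
        and nucleus at ``background + gain * nc * cyto_level``.
    stain_level:
        Mean nuclear-stain intensity above background.
    texture_sd:
        Relative amplitude of the smooth intranuclear stain texture.
    overlap_tol_px:
        Allowed overlap (centre distance shortfall) between nuclei, pixels.
    cyto_extent_px:
        Cytoplasm reaches this far (pixels) from the nucleus boundary; the
        rest of the field is cell-free background.  ``None`` renders a
        confluent monolayer whose cytoplasm fills the whole field.
    conserve_total:
        If True, per-cell cytoplasm territories are rendered with a
        concentration that conserves the cell's total reporter content as
        N/C changes (redistribution only).  If False (default) the cytoplasm
        is a uniform pool at ``cyto_level``.
    seed:
        RNG seed; fixed seed implies byte-identical output.
    """

    shape: tuple[int, int, int, int] = (20, 1, 256, 256)
    pixel_size_um: float = 0.276
    frame_interval: float = 3.0
    n_cells: int = 12
    semiaxes_px: tuple[float, float] = (9.0, 14.0)
    step_sigma_px: float = 1.0
    nucleolus_fraction: float = 0.12
    nucleolus_dim: float = 0.35
    background: float = 100.0
    camera_offset: float = 0.0
    poisson_gain: float = 0.0
    read_noise_sd: float = 0.0
    reporter_gain: float = 1.0
    cyto_level: float = 200.0
    stain_level: float = 600.0
    texture_sd: float = 0.10
    overlap_tol_px: float = 2.0
    cyto_extent_px: float | None = 18.0
    conserve_total: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.shape) or len(self.shape) != 4:
            raise ValueError("shape must be four positive integers (T, Z, Y, X)")
        if not (0.0 <= self.nucleolus_fraction < 1.0):
            raise ValueError("nucleolus_fraction must lie in [0, 1)")
        if self.pixel_size_um <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.semiaxes_px[0] <= 0 or self.semiaxes_px[1] < self.semiaxes_px[0]:
            raise ValueError("invalid nucleus semi-axis range")


@dataclass(frozen=True)
class NCEvent:
    """One programmed localization event on a cell's N/C series.

    ``reset`` is a symmetric dip (nuclear exodus then re-entry), ``ramp`` a
    sustained linear shift by ``amplitude``, ``stagnation`` a flat hold.
    """

    onset: int
    kind: str  # "reset" | "ramp" | "stagnation"
    amplitude: float = 0.0
    duration: int = 6

    def __post_init__(self) -> None:
        if self.kind not in ("reset", "ramp", "stagnation"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration < 1:
            raise ValueError("event duration must be >= 1 frame")


@dataclass(frozen=True)
class NCProgram:
    """Per-cell baseline N/C and programmed events (non-overlapping)."""

    baselines: tuple[float, ...]
    events: tuple[tuple[NCEvent, ...], ...] = ()

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.baselines):
            raise ValueError("baseline N/C must be positive")
        for evs in self.events:
            spans = sorted((e.onset, e.onset + e.duration) for e in evs)
            for (s0, e0), (s1, _) in zip(spans, spans[1:]):
                if s1 < e0:
                    raise ValueError("programmed events overlap")

    @classmethod
    def constant(cls, n_cells: int, nc: float = 1.0) -> "NCProgram":
        return cls(baselines=(float(nc),) * n_cells)


def nc_series(baseline: float, events: tuple[NCEvent, ...], n_frames: int) -> np.ndarray:
    """Realize a programmed N/C time series of length ``n_frames``.

    Resets are rendered as a triangular dip of depth ``amplitude`` over
    ``duration`` frames; ramps shift the level linearly by ``amplitude`` and
    hold; stagnations hold the current level.
    """
    nc = np.full(n_frames, float(baseline))
    offset = 0.0
    for ev in sorted(events, key=lambda e: e.onset):
        t0, d = ev.onset, ev.duration
        if t0 >= n_frames:
            continue
        if ev.kind == "reset":
            half = max(d // 2, 1)
            for k in range(d + 1):
                t = t0 + k
                if 0 <= t < n_frames:
                    depth = ev.amplitude * (1 - abs(k - half) / half)
                    nc[t] = baseline + offset - depth
        elif ev.kind == "ramp":
            for k in range(d + 1):
                t = t0 + k
                if 0 <= t < n_frames:
                    nc[t] = baseline + offset + ev.amplitude * k / d
            nc[min(t0 + d, n_frames - 1):] = baseline + offset + ev.amplitude
            offset += ev.amplitude
        # "stagnation": hold current level; nothing to do
    if np.any(nc <= 0):
        raise ValueError("programmed N/C series must stay positive")
    return nc


@dataclass(frozen=True)
class BurstProgram:
    """Telegraph (two-state) transcription parameters per cell.

    ``on_rate``/``off_rate`` are per-frame switching probabilities; a cell in
    the "on" state carries one nascent locus of total ``intensity`` photons
    rendered as a Gaussian of width ``psf_sigma_px`` at a fixed position
    inside its nucleus.
    """

    on_rate: tuple[float, ...]
    off_rate: tuple[float, ...]
    intensity: float = 2000.0
    psf_sigma_px: float = 1.5
    mcp_background: float = 60.0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.on_rate + self.off_rate):
            raise ValueError("telegraph rates must be >= 0")
        if self.psf_sigma_px < 0.5:
            raise ValueError("PSF sigma must be >= 0.5 px")

    @classmethod
    def uniform(cls, n_cells: int, on_rate: float, off_rate: float, **kw) -> "BurstProgram":
        return cls(on_rate=(on_rate,) * n_cells, off_rate=(off_rate,) * n_cells, **kw)


@dataclass(frozen=True)
class DivisionEvent:
    parent: int
    frame: int


@dataclass
class Movie:
    """Multi-channel time-lapse: ``data`` has shape (T, C, Z, Y, X)."""

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size_um: float
    frame_interval: float

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channels.index(name)]


@dataclass
class GroundTruth:
    """Everything the generator knows about what it rendered."""

    labels: np.ndarray  # (T, Z, Y, X) int32 per-frame nucleus label maps
    tracks: pd.DataFrame  # cell, frame, z, y, x, label
    nc: np.ndarray | None = None  # (n_cells, T) programmed N/C
    nc_program: NCProgram | None = None
    burst_states: np.ndarray | None = None  # (n_cells, T) bool
    spot_positions: np.ndarray | None = None  # (n_cells, 3) z, y, x offsets
    divisions: tuple[DivisionEvent, ...] = ()
    division_records: pd.DataFrame | None = None
    kinetics: dict = field(default_factory=dict)


# ----------------------------------------------------------------- placement


def _place_centres(cfg: SceneConfig, semiaxes: np.ndarray, rng: np.random.Generator,
                   max_tries: int = 2000) -> np.ndarray:
    """Rejection-sample non-overlapping nucleus centres (y, x)."""
    _, _, ny, nx = cfg.shape
    centres = np.empty((cfg.n_cells, 2))
    radii = semiaxes.max(axis=1)
    placed = 0
    for _ in range(max_tries):
        r = radii[placed]
        c = rng.uniform([r + 1, r + 1], [ny - r - 1, nx - r - 1])
        if placed == 0:
            ok = True
        else:
            d = np.hypot(*(centres[:placed] - c).T)
            ok = np.all(d >= radii[:placed] + r - cfg.overlap_tol_px)
        if ok:
            centres[placed] = c
            placed += 1
            if placed == cfg.n_cells:
                return centres
    raise PlacementError(
        f"could only place {placed}/{cfg.n_cells} nuclei without overlap; "
        "reduce n_cells or nucleus size"
    )


def _walk(cfg: SceneConfig, centres: np.ndarray, semiaxes: np.ndarray,
          rng: np.random.Generator) -> np.ndarray:
    """Reflected Gaussian random walk, rejecting steps that collide."""
    nt = cfg.shape[0]
    _, _, ny, nx = cfg.shape
    radii = semiaxes.max(axis=1)
    paths = np.empty((nt, cfg.n_cells, 2))
    paths[0] = centres
    for t in range(1, nt):
        cur = paths[t - 1].copy()
        for i in range(cfg.n_cells):
            for _ in range(10):
                step = rng.normal(0.0, cfg.step_sigma_px, 2)
                cand = cur[i] + step
                # reflect at image borders (keep the whole nucleus inside)
                r = radii[i]
                lo, hi = r + 1, np.array([ny, nx]) - r - 1
                cand = np.where(cand < lo, 2 * lo - cand, cand)
                cand = np.where(cand > hi, 2 * hi - cand, cand)
                others = np.delete(np.arange(cfg.n_cells), i)
                d = np.hypot(*(cur[others] - cand).T)
                if np.all(d >= radii[others] + r - cfg.overlap_tol_px):
                    cur[i] = cand
                    break
            # on persistent collision the nucleus simply stays put this frame
        paths[t] = cur
    return paths


def _boundary_jitter(rng: np.random.Generator, n_modes: int = 3,
                     amplitude: float = 0.04) -> tuple[np.ndarray, np.ndarray]:
    amps = rng.uniform(0, amplitude, n_modes)
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    return amps, phases


def _nucleus_mask(shape_zyx: tuple[int, int, int], centre: np.ndarray,
                  semiaxes: np.ndarray, jitter: tuple[np.ndarray, np.ndarray]) -> tuple:
    """Rasterize one (possibly single-plane) ellipsoidal nucleus.

    Returns a bounding-box slice tuple and the boolean mask within it.  The
    in-plane radius is modulated by a low-order Fourier series for a smooth,
    non-elliptical boundary.
    """
    nz, ny, nx = shape_zyx
    az, ay, ax = semiaxes
    cy, cx = centre
    cz = (nz - 1) / 2.0
    z0, z1 = (0, nz) if nz == 1 else (max(int(cz - az), 0), min(int(cz + az) + 2, nz))
    y0, y1 = max(int(cy - ay) - 2, 0), min(int(cy + ay) + 3, ny)
    x0, x1 = max(int(cx - ax) - 2, 0), min(int(cx + ax) + 3, nx)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    amps, phases = jitter
    mod = 1.0 + sum(a * np.cos((k + 2) * theta + p)
                    for k, (a, p) in enumerate(zip(amps, phases)))
    rho2 = (dy / (ay * mod)) ** 2 + (dx / (ax * mod)) ** 2
    if nz > 1:
        rho2 = rho2 + ((zz - cz) / az) ** 2
    return (slice(z0, z1), slice(y0, y1), slice(x0, x1)), rho2 <= 1.0


def _nucleolus_mask(mask: np.ndarray, fraction: float,
                    rng: np.random.Generator) -> np.ndarray:
    """A blob inside ``mask`` occupying ~``fraction`` of its pixels.

    Built as a small ellipsoid around an interior point, grown/shrunk to the
    requested pixel count by distance thresholding.
    """
    if fraction <= 0:
        return np.zeros_like(mask)
    idx = np.argwhere(mask)
    centre = idx.mean(axis=0)
    # random interior offset, biased toward the centre so the blob fits
    pick = idx[rng.integers(len(idx))]
    anchor = 0.6 * centre + 0.4 * pick
    d2 = ((idx - anchor) ** 2).sum(axis=1)
    k = max(int(round(fraction * len(idx))), 1)
    order = np.argsort(d2, kind="stable")[:k]
    out = np.zeros_like(mask)
    out[tuple(idx[order].T)] = True
    return out


def _apply_noise(img: np.ndarray, cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    out = img
    if cfg.poisson_gain > 0:
        out = rng.poisson(np.clip(out, 0, None) * cfg.poisson_gain) / cfg.poisson_gain
    if cfg.read_noise_sd > 0:
        out = out + rng.normal(0.0, cfg.read_noise_sd, out.shape)
    return out + cfg.camera_offset


def _split_division(semiax: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Daughter semi-axes: two nuclei of ~half the parent area."""
    return semiax / np.sqrt(2.0), semiax / np.sqrt(2.0)


# ----------------------------------------------------------- monolayer movie


def generate_monolayer_movie(
    config: SceneConfig,
    program: NCProgram | None = None,
    divisions: tuple[DivisionEvent, ...] = (),
) -> tuple[Movie, GroundTruth]:
    """Render a two-channel (stain, reporter) monolayer movie.

    The reporter channel realizes, per cell and before noise,
    ``nuclear mean = background + gain * nc(t) * cyto_level`` and
    ``cytoplasmic mean = background + gain * cyto_level`` (or the
    conservation-preserving per-cell equivalent when
    ``config.conserve_total`` is set).  Nucleoli are rendered as dimmed
    subregions of the configured fractional size in both channels.

    Divisions replace the parent nucleus with two adjacent daughters from
    the annotated frame on; daughters get fresh track ids and inherit the
    parent's N/C program.
    """
    if program is None:
        program = NCProgram.constant(config.n_cells)
    if len(program.baselines) > config.n_cells:
        raise ValueError("program has more cells than the scene")

    rng = np.random.default_rng(config.seed)
    nt, nz, ny, nx = config.shape
    n = config.n_cells
    semiaxes = np.empty((n, 3))
    semiaxes[:, 1:] = rng.uniform(*config.semiaxes_px, size=(n, 2))
    semiaxes[:, 0] = max(nz / 3.0, 1.0)  # nucleus spans ~3 of the z planes
    centres = _place_centres(config, semiaxes[:, 1:], rng)
    paths = _walk(config, centres, semiaxes[:, 1:], rng)
    jitters = [_boundary_jitter(rng) for _ in range(n)]

    nc_mat = np.ones((n, nt))
    for i in range(n):
        base = program.baselines[i] if i < len(program.baselines) else 1.0
        evs = program.events[i] if i < len(program.events) else ()
        nc_mat[i] = nc_series(base, evs, nt)

    # stable smooth texture field per cell (sampled once, moves with the cell)
    textures = rng.normal(1.0, config.texture_sd, size=(n,))

    div_by_frame: dict[int, list[DivisionEvent]] = {}
    for d in divisions:
        div_by_frame.setdefault(d.frame, []).append(d)
    next_id = n + 1
    daughter_of: dict[int, tuple[int, int, int]] = {}  # parent -> (d1, d2, frame)

    data = np.zeros((nt, 2, nz, ny, nx))
    labels = np.zeros((nt, nz, ny, nx), dtype=np.int32)
    rows = []
    div_rows = []

    # per-frame alive set: cell index -> (track_id, centre shift, scale)
    alive: dict[int, list] = {i: [(i + 1, np.zeros(2), 1.0)] for i in range(n)}

    for t in range(nt):
        for d in div_by_frame.get(t, ()):
            i = d.parent
            if i in daughter_of or i >= n:
                continue
            d1, d2 = next_id, next_id + 1
            next_id += 2
            daughter_of[i] = (d1, d2, t)
            ang = rng.uniform(0, 2 * np.pi)
            sep = semiaxes[i, 1:].max() / np.sqrt(2.0) + 0.5
            off = np.array([np.sin(ang), np.cos(ang)]) * sep
            alive[i] = [(d1, off, 1 / np.sqrt(2.0)), (d2, -off, 1 / np.sqrt(2.0))]
            div_rows.append({"parent_id": i + 1, "daughter1_id": d1,
                             "daughter2_id": d2, "cytokinesis_frame": t})

        stain = np.full((nz, ny, nx), config.background, dtype=float)
        reporter = np.full((nz, ny, nx), config.background, dtype=float)
        cyto_add = np.zeros((nz, ny, nx))
        nuc_masks = []
        for i in range(n):
            for track_id, off, scale in alive[i]:
                ctr = paths[t, i] + off
                sem = semiaxes[i].copy()
                sem[1:] *= scale
                box, m = _nucleus_mask((nz, ny, nx), ctr, sem, jitters[i])
                if not m.any():
                    continue
                labels[t][box][m] = track_id
                nuc_masks.append((i, track_id, box, m, ctr))

        from scipy import ndimage as ndi

        whole_cyto = labels[t] == 0
        if config.cyto_extent_px is not None:
            # cytoplasm occupies a bounded halo around each nucleus; the
            # remaining field is cell-free fluorescence background
            dist = ndi.distance_transform_edt(whole_cyto)
            cyto_mask = whole_cyto & (dist <= config.cyto_extent_px)
        else:
            cyto_mask = whole_cyto
        nc_t = nc_mat[:, t]
        if config.conserve_total:
            # per-cell cytoplasm territories: nearest-nucleus partition
            _, (iz, iy, ix) = ndi.distance_transform_edt(
                whole_cyto, return_indices=True
            )
            territory = labels[t][iz, iy, ix]
        for i, track_id, box, m, ctr in nuc_masks:
            nuci = _nucleolus_mask(m, config.nucleolus_fraction, np.random.default_rng(
                config.seed * 1000 + i))
            tex = textures[i]
            stain_val = config.stain_level * tex
            stain[box][m] += stain_val
            stain[box][nuci] -= stain_val * (1 - config.nucleolus_dim)
            if config.conserve_total:
                # conserve total reporter: N*Vn + C*Vc fixed as nc(t) varies
                vn = m.sum()
                terr = (territory == track_id) & cyto_mask
                vc = max(terr.sum(), 1)
                total = config.cyto_level * (vc + 1.0 * vn)  # content at nc=1
                c_i = total / (vc + nc_t[i] * vn)
                reporter[box][m] += config.reporter_gain * nc_t[i] * c_i
                cyto_add[terr] = config.reporter_gain * c_i
            else:
                reporter[box][m] += config.reporter_gain * nc_t[i] * config.cyto_level
            # reporter excluded from nucleolus: dim toward background
            rep_val = reporter[box][m].max() - config.background
            reporter[box][nuci] -= rep_val * (1 - config.nucleolus_dim)
            rows.append({"cell": track_id, "frame": t, "z": (nz - 1) / 2.0,
                         "y": ctr[0], "x": ctr[1], "label": track_id})
        if config.conserve_total:
            reporter[cyto_mask] += cyto_add[cyto_mask]
        else:
            reporter[cyto_mask] += config.reporter_gain * config.cyto_level

        data[t, 0] = _apply_noise(stain, config, rng)
        data[t, 1] = _apply_noise(reporter, config, rng)

    movie = Movie(data=data, channels=("stain", "reporter"),
                  pixel_size_um=config.pixel_size_um,
                  frame_interval=config.frame_interval)
    gt = GroundTruth(
        labels=labels,
        tracks=pd.DataFrame(rows),
        nc=nc_mat,
        nc_program=program,
        divisions=tuple(divisions),
        division_records=pd.DataFrame(
            div_rows, columns=["parent_id", "daughter1_id", "daughter2_id",
                               "cytokinesis_frame"]),
    )
    return movie, gt


# ----------------------------------------------------------------- spot movie


def generate_spot_movie(
    config: SceneConfig,
    bursts: BurstProgram,
    program: NCProgram | None = None,
) -> tuple[Movie, GroundTruth]:
    """Render stain + reporter + spot channels with telegraph bursting.

    The spot channel carries diffuse nuclear MCP background plus, in "on"
    frames, a Gaussian focus of the programmed integrated intensity at a
    fixed intranuclear offset per cell.  Realized on/off state sequences are
    exported as ground truth.
    """
    n = config.n_cells
    if len(bursts.on_rate) != n:
        raise ValueError("burst program size must match n_cells")
    movie, gt = generate_monolayer_movie(config, program)
    rng = np.random.default_rng(config.seed + 7919)
    nt, nz, ny, nx = config.shape

    # telegraph chains, stationary initial state
    states = np.zeros((n, nt), dtype=bool)
    for i in range(n):
        kon, koff = bursts.on_rate[i], bursts.off_rate[i]
        p_on = kon / (kon + koff) if (kon + koff) > 0 else 0.0
        s = rng.random() < p_on
        for t in range(nt):
            states[i, t] = s
            if s:
                s = not (rng.random() < koff)
            else:
                s = rng.random() < kon
    # fixed intranuclear spot offset per cell (relative to centroid)
    offsets = np.zeros((n, 3))
    for i in range(n):
        offsets[i, 1:] = rng.uniform(-0.4, 0.4, 2) * min(config.semiaxes_px)

    sigma = bursts.psf_sigma_px
    half = int(np.ceil(4 * sigma))
    zz = np.arange(-half, half + 1)
    spot_kernel = np.exp(-(zz[:, None] ** 2 + zz[None, :] ** 2) / (2 * sigma**2))
    spot_kernel = spot_kernel / spot_kernel.sum() * bursts.intensity

    spot = np.full((nt, 1, nz, ny, nx), config.background, dtype=float)
    tracks = gt.tracks.set_index(["cell", "frame"])
    zc = (nz - 1) // 2
    for t in range(nt):
        # diffuse nuclear MCP signal
        spot[t, 0][gt.labels[t] > 0] += bursts.mcp_background
        for i in range(n):
            if not states[i, t]:
                continue
            try:
                row = tracks.loc[(i + 1, t)]
            except KeyError:
                continue
            cy = row["y"] + offsets[i, 1]
            cx = row["x"] + offsets[i, 2]
            iy, ix = int(round(cy)), int(round(cx))
            y0, y1 = iy - half, iy + half + 1
            x0, x1 = ix - half, ix + half + 1
            if y0 < 0 or x0 < 0 or y1 > ny or x1 > nx:
                continue
            if gt.labels[t, zc, iy, ix] != i + 1:
                raise ValueError("programmed spot position outside its nucleus")
            spot[t, 0, zc, y0:y1, x0:x1] += spot_kernel

    noise_rng = np.random.default_rng(config.seed + 104729)
    for t in range(nt):
        spot[t, 0] = _apply_noise(spot[t, 0], config, noise_rng)

    data = np.concatenate([movie.data, spot], axis=1)
    out = Movie(data=data, channels=("stain", "reporter", "spot"),
                pixel_size_um=config.pixel_size_um,
                frame_interval=config.frame_interval)
    gt.burst_states = states
    gt.spot_positions = offsets
    gt.kinetics["burst_program"] = bursts
    return out, gt


# ------------------------------------------------------- compartment bleach


def simulate_compartment_bleach(
    k_import: float,
    k_export: float,
    bleach_target: str,
    sampling: np.ndarray,
    residual_fraction: float = 0.0,
    pre_nuclear: float | None = None,
    pre_cyto: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Two-pool nucleocytoplasmic exchange after a compartment bleach.

    Integrates ``dN/dt = k_import * C - k_export * N`` (and the mirrored
    cytoplasmic equation) from the postbleach initial condition, where the
    bleached pool starts at ``residual_fraction`` of its prebleach value.
    The system is linear, so the exact closed-form solution is used:
    ``N(t) = N_inf + (N0 - N_inf) exp(-(k_import + k_export) t)`` with
    ``N_inf = k_import (N0 + C0) / (k_import + k_export)``.

    Prebleach levels default to the exchange equilibrium
    ``N/C = k_import/k_export`` with cytoplasm at 1 (or to 1/1 when a rate
    is zero).

    Returns ``(nuclear trace at sampling times, N0, C0)`` where N0/C0 are the
    postbleach nuclear and cytoplasmic intensities.
    """
    if k_import < 0 or k_export < 0:
        raise ValueError("transport rates must be >= 0")
    t = np.asarray(sampling, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("sampling times must be strictly increasing")
    if bleach_target not in ("nucleus", "cytoplasm"):
        raise ValueError("bleach_target must be 'nucleus' or 'cytoplasm'")

    if pre_cyto is None:
        pre_cyto = 1.0
    if pre_nuclear is None:
        pre_nuclear = k_import / k_export if k_export > 0 else 1.0

    n0 = pre_nuclear * (residual_fraction if bleach_target == "nucleus" else 1.0)
    c0 = pre_cyto * (residual_fraction if bleach_target == "cytoplasm" else 1.0)

    lam = k_import + k_export
    if lam == 0:
        return np.full_like(t, n0), n0, c0
    n_inf = k_import * (n0 + c0) / lam
    trace = n_inf + (n0 - n_inf) * np.exp(-lam * (t - t[0]))
    return trace, n0, c0
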