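"""Simplified voxel torso volume conductor and electrode placement.

The torso is an elliptic cylinder on a regular cell-centered voxel grid
(right-handed axes: x = subject's left, y = cranial, z = anterior; all
physical coordinates in cm).  From the surface inward the passive tissues
are a subcutaneous fat shell, a muscle shell, a rib-cage bone shell over
the thoracic band, and homogeneous torso bulk; two ellipsoidal lungs and
a two-chamber heart are embedded in the bulk.

The heart is built from two stacked ellipsoidal shells, an atrial shell
(ATR) above a ventricular shell (VTR), each enclosing a BLOOD cavity.
The conduction system is laid along the activation path: a sinoatrial
node cluster (SAN) in the atrial roof, an atrioventricular node (AVN)
bridging the electrically insulating gap between the shells, the His
bundle (HIS) beneath it, a bundle-branch column (BNL) descending through
the ventricular cavity, and a Purkinje layer (PKJ) lining the inner
ventricular wall so that ventricular activation spreads endocardium
outward.  All regions are defined by analytic shapes in physical units,
so subdomain volume fractions converge under grid refinement.

Electrode geometry follows the Einthoven triangle in the Mason-Likar
torso placement: LA/RA in the infraclavicular fossae separated by the
inter-clavipectoral-triangle distance Wh, LL above the left iliac crest
at the umbilical level (a vertical drop Wv below the sternal angle), and
RL mirrored on the right as the reference (VGND = 0) electrode.
Displaced measurement configurations 1-6 contract the triangle toward
its centroid: every active electrode moves a whole number of horizontal
steps f*Wh and vertical steps f*Wv (f = 0.125 by default), with the step
counts per position chosen so the displacement magnitude grows strictly
with the position index.  Position 0 is the unmodified reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# labels and electrical properties

EXTERIOR = 0
TORSO = 1
MUSCLE = 2
FAT = 3
BONE = 4
LUNG = 5
BLOOD = 6
SAN = 7
ATR = 8
AVN = 9
HIS = 10
BNL = 11
PKJ = 12
VTR = 13

LABEL_NAMES = {
    EXTERIOR: "EXTERIOR", TORSO: "TORSO", MUSCLE: "MUSCLE", FAT: "FAT",
    BONE: "BONE", LUNG: "LUNG", BLOOD: "BLOOD", SAN: "SAN", ATR: "ATR",
    AVN: "AVN", HIS: "HIS", BNL: "BNL", PKJ: "PKJ", VTR: "VTR",
}
HEART_LABELS = (SAN, ATR, AVN, HIS, BNL, PKJ, VTR)

#: Passive conductivity sigma0 per subdomain, mS/m.  Heart subdomains share
#: the averaged whole-heart value in the passive (Laplace) domain.
SIGMA0_MS_PER_M = {
    TORSO: 200.0,
    MUSCLE: 200.0,
    FAT: 40.0,
    BONE: 6.0,
    LUNG: 40.0,
    BLOOD: 700.0,
    **{lab: 50.0 for lab in HEART_LABELS},
}


@dataclass
class GeometryConfig:
    """Analytic description of the torso model, lengths in cm."""

    shape: tuple = (40, 48, 24)
    spacing: float = 1.0
    torso_semi_x: float = 17.0
    torso_semi_z: float = 10.5
    fat_thickness: float = 2.0
    muscle_thickness: float = 2.0
    bone_thickness: float = 1.5
    rib_band: tuple = (22.0, 46.0)       # y-range of the rib cage
    lung_center: tuple = (7.5, 34.0, 0.5)  # mirrored in x for the other lung
    lung_semi: tuple = (5.0, 10.5, 6.5)
    atr_center: tuple = (2.0, 33.5, 1.5)
    atr_semi: tuple = (3.4, 3.0, 3.4)
    atr_wall: float = 1.3
    vtr_center: tuple = (2.0, 27.0, 1.5)
    vtr_semi: tuple = (4.6, 5.0, 4.6)
    vtr_wall: float = 1.9
    pkj_fraction: float = 0.45           # inner fraction of the VTR wall
    av_gap: float = 1.2                  # insulating gap between ATR and VTR
    node_radius: float = 1.1             # SAN/AVN/HIS cluster radius
    bnl_radius: float = 0.9              # bundle-branch column radius
    avn_offset: float = 1.6              # AV column axis offset from SAN (cm)
    include_organs: bool = True

    @classmethod
    def from_yaml(cls, path) -> "GeometryConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown geometry config keys: {sorted(unknown)}")
        for key in ("shape", "rib_band", "lung_center", "lung_semi",
                    "atr_center", "atr_semi", "vtr_center", "vtr_semi"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


@dataclass
class TorsoGeometry:
    """Labeled voxel volume conductor."""

    labels: np.ndarray            # (nx, ny, nz) int labels
    spacing: float                # cm
    config: GeometryConfig

    @property
    def shape(self):
        return self.labels.shape

    @property
    def sigma0(self) -> np.ndarray:
        """Passive conductivity per cell in mS/m (0 outside the body)."""
        out = np.zeros(self.labels.shape)
        for lab, sig in SIGMA0_MS_PER_M.items():
            out[self.labels == lab] = sig
        return out

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels != EXTERIOR

    @property
    def heart_mask(self) -> np.ndarray:
        return np.isin(self.labels, HEART_LABELS)

    @property
    def surface_mask(self) -> np.ndarray:
        """Body cells with at least one exterior/out-of-grid face."""
        body = self.body_mask
        padded = np.pad(body, 1, constant_values=False)
        interior = np.ones_like(body)
        for axis in range(3):
            for shift in (-1, 1):
                interior &= np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
        return body & ~interior

    def cell_centers(self):
        """Physical coordinates (cm) of cell centers along each axis."""
        nx, ny, nz = self.shape
        h = self.spacing
        x = (np.arange(nx) + 0.5) * h - nx * h / 2.0
        y = (np.arange(ny) + 0.5) * h
        z = (np.arange(nz) + 0.5) * h - nz * h / 2.0
        return x, y, z

    def volume_fractions(self) -> dict:
        body = int(self.body_mask.sum())
        out = {}
        for lab, name in LABEL_NAMES.items():
            if lab == EXTERIOR:
                continue
            n = int((self.labels == lab).sum())
            if n:
                out[name] = n / body
        return out

    def save(self, path) -> None:
        """HDF5 labeled array plus a JSON metadata sidecar."""
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("labels", data=self.labels, compression="gzip")
            f.attrs["spacing_cm"] = self.spacing
        meta = {"spacing_cm": self.spacing, "config": asdict(self.config),
                "label_names": {str(k): v for k, v in LABEL_NAMES.items()}}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "TorsoGeometry":
        import h5py

        path = Path(path)
        with h5py.File(path, "r") as f:
            labels = f["labels"][()]
            spacing = float(f.attrs["spacing_cm"])
        meta = json.loads(path.with_suffix(".json").read_text())
        cfgdata = meta["config"]
        for key, val in cfgdata.items():
            if isinstance(val, list):
                cfgdata[key] = tuple(val)
        return cls(labels=labels, spacing=spacing,
                   config=GeometryConfig(**cfgdata))


def _ellipsoid(X, Y, Z, center, semi):
    cx, cy, cz = center
    sx, sy, sz = semi
    return (((X - cx) / sx) ** 2 + ((Y - cy) / sy) ** 2
            + ((Z - cz) / sz) ** 2) <= 1.0


def build_torso_geometry(config: GeometryConfig | None = None) -> TorsoGeometry:
    """Build the labeled voxel volume conductor from an analytic config."""
    cfg = config or GeometryConfig()
    nx, ny, nz = cfg.shape
    if min(nx, ny, nz) < 16:
        raise ValueError("grid resolution must be >= 16 cells per axis")
    h = cfg.spacing

    geom = TorsoGeometry(labels=np.zeros(cfg.shape, dtype=np.int8),
                         spacing=h, config=cfg)
    x, y, z = geom.cell_centers()
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    ax, az = cfg.torso_semi_x, cfg.torso_semi_z

    def torso_ring(shrink):
        a, c = ax - shrink, az - shrink
        return (X / a) ** 2 + (Z / c) ** 2 <= 1.0

    labels = geom.labels
    body = torso_ring(0.0)
    labels[body] = TORSO

    if cfg.include_organs:
        # concentric shells, outermost first
        t_fat = cfg.fat_thickness
        t_mus = t_fat + cfg.muscle_thickness
        t_bone = t_mus + cfg.bone_thickness
        labels[body & ~torso_ring(t_fat)] = FAT
        labels[torso_ring(t_fat) & ~torso_ring(t_mus)] = MUSCLE
        rib = (Y >= cfg.rib_band[0]) & (Y <= cfg.rib_band[1])
        labels[torso_ring(t_mus) & ~torso_ring(t_bone) & rib] = BONE

        interior = labels == TORSO
        lx, ly, lz = cfg.lung_center
        for sx in (+1, -1):
            lung = _ellipsoid(X, Y, Z, (sx * lx, ly, lz), cfg.lung_semi)
            labels[lung & interior] = LUNG

        _build_heart(labels, X, Y, Z, cfg, interior)

    if not np.isin(labels, HEART_LABELS).any() and cfg.include_organs:
        raise ValueError("heart region is empty at this resolution")
    return geom


def _build_heart(labels, X, Y, Z, cfg: GeometryConfig, interior):
    """Stacked atrial/ventricular shells with the conduction path."""
    vtr_outer = _ellipsoid(X, Y, Z, cfg.vtr_center, cfg.vtr_semi)
    inner_semi = tuple(max(s - cfg.vtr_wall, 0.3) for s in cfg.vtr_semi)
    vtr_inner = _ellipsoid(X, Y, Z, cfg.vtr_center, inner_semi)
    pkj_semi = tuple(min(si + cfg.pkj_fraction * cfg.vtr_wall, so)
                     for si, so in zip(inner_semi, cfg.vtr_semi))
    pkj_zone = _ellipsoid(X, Y, Z, cfg.vtr_center, pkj_semi)

    place = interior | np.isin(labels, (LUNG,))
    labels[vtr_outer & place] = VTR
    vtr_now = labels == VTR
    labels[pkj_zone & vtr_now] = PKJ
    labels[vtr_inner & (vtr_now | (labels == PKJ))] = BLOOD

    # atrial shell, kept clear of the ventricle by the AV gap
    gap_semi = tuple(s + cfg.av_gap for s in cfg.vtr_semi)
    vtr_gap = _ellipsoid(X, Y, Z, cfg.vtr_center, gap_semi)
    atr_outer = _ellipsoid(X, Y, Z, cfg.atr_center, cfg.atr_semi)
    atr_inner_semi = [max(s - cfg.atr_wall, 0.3) for s in cfg.atr_semi]
    atr_inner = _ellipsoid(X, Y, Z, cfg.atr_center, atr_inner_semi)
    atr_zone = atr_outer & ~vtr_gap
    labels[atr_zone & (interior | (labels == LUNG))] = ATR
    labels[atr_inner & (labels == ATR)] = BLOOD

    # The SAN is a cap at the atrial roof apex, protruding into the
    # passive surroundings so most of the node is electrically insulated
    # (as the real node is, apart from its atrial exits): an exposed node
    # would be phase-dispersed by the atrial load and lose its rhythm.
    cx, cy_atr, czc = cfg.atr_center
    san_center = (cx, cy_atr + cfg.atr_semi[1], czc)
    san = _ellipsoid(X, Y, Z, san_center, (1.2 * cfg.node_radius,) * 3)
    san_ok = np.isin(labels, (EXTERIOR, TORSO, LUNG, ATR, BLOOD)) & \
        (interior | np.isin(labels, (ATR, BLOOD)))
    labels[san & san_ok] = SAN

    # Conduction path, routed through the blood-insulated cavities so the
    # narrow columns are not current-loaded by the working myocardium:
    # the AVN column descends from beneath the atrial roof through the AV
    # gap; the His column (stronger coupling) takes over just above the
    # ventricular roof, crosses the wall and continues into the cavity;
    # the bundle column runs to the apex and fans into a cap lining the
    # lower endocardium, so the Purkinje layer is driven over a broad
    # quasi-planar contact rather than from a point.
    vx, vy, vz = cfg.vtr_center
    y_top_vtr = vy + cfg.vtr_semi[1]
    inner_sy = inner_semi[1]
    r_col = 0.8 * cfg.node_radius
    # column axis offset from the SAN cap so the node only talks to the
    # AVN through the atrial wall, not directly
    ax_x = vx - cfg.avn_offset
    radial = ((X - ax_x) ** 2 + (Z - vz) ** 2) <= r_col ** 2
    y_avn_top = cfg.atr_center[1] + atr_inner_semi[1] + 0.6
    y_avn_bot = y_top_vtr + 0.2
    y_his_bot = vy + inner_sy - 1.5
    y_apex = vy - inner_sy + 0.5

    allowed = interior | np.isin(labels, (ATR, VTR, PKJ, BLOOD))
    replaceable = np.isin(labels, (EXTERIOR, TORSO, LUNG, ATR, VTR, PKJ,
                                   BLOOD)) & allowed
    avn = radial & (Y > y_avn_bot) & (Y <= y_avn_top)
    labels[avn & replaceable] = AVN
    his = radial & (Y > y_his_bot) & (Y <= y_avn_bot)
    labels[his & replaceable] = HIS
    bnl = radial & (Y > y_apex) & (Y <= y_his_bot)
    cap_semi = [max(s - 0.75, 0.2) for s in inner_semi]
    cap = vtr_inner & ~_ellipsoid(X, Y, Z, cfg.vtr_center, cap_semi) & \
        (Y < vy - 0.25 * inner_sy)
    labels[(bnl | cap) & (labels == BLOOD)] = BNL


# ---------------------------------------------------------------------------
# electrode placement

#: (horizontal, vertical) step counts applied at each measurement position.
#: Chosen so the per-position displacement magnitude grows strictly with the
#: index: with the cohort-average steps (3.6, 5.4) cm the distances are
#: 0, 3.6, 5.4, 6.5, 9.0, 11.4 and 13.0 cm.
POSITION_STEPS = {
    0: (0, 0),
    1: (1, 0),
    2: (0, 1),
    3: (1, 1),
    4: (2, 1),
    5: (1, 2),
    6: (2, 2),
}


@dataclass
class ElectrodeLayout:
    """Surface electrode coordinates for every measurement configuration.

    ``electrodes[(side, position)]`` maps electrode name (LA/RA/LL/RL) to
    a voxel index triple on the requested surface; ``anchors`` holds the
    corresponding physical (x, y) anatomical coordinates in cm.  RL is the
    fixed reference electrode and does not move with position.
    """

    Wh: float
    Wv: float
    f: float
    electrodes: dict = field(default_factory=dict)
    anchors: dict = field(default_factory=dict)

    @property
    def step_cm(self) -> tuple:
        """Per-step displacement (horizontal, vertical) in cm."""
        return (self.f * self.Wh, self.f * self.Wv)

    def displacement(self, position: int) -> tuple:
        kh, kv = POSITION_STEPS[position]
        dh, dv = self.step_cm
        return (kh * dh, kv * dv)

    def distance_from_reference(self, position: int) -> float:
        return float(np.hypot(*self.displacement(position)))


def place_electrodes(geometry: TorsoGeometry, Wh: float = 28.8,
                     Wv: float = 43.2, f: float = 0.125) -> ElectrodeLayout:
    """Project the Einthoven/Mason-Likar electrode sets onto the surface.

    ``Wh`` is the inter-clavipectoral-triangle distance, ``Wv`` the
    sternal-angle-to-umbilical distance (both cm); ``f`` is the step
    fraction.  Raises if any electrode leaves the torso surface, naming
    the offending point.
    """
    if Wh <= 0 or Wv <= 0:
        raise ValueError("anthropometric distances must be positive")
    if not 0 <= f < 0.5:
        raise ValueError("step fraction must satisfy 0 <= f < 0.5")

    ny = geometry.shape[1]
    h = geometry.spacing
    y_clav = ny * h - 4.0          # infraclavicular level
    y_ll = y_clav - Wv             # umbilical level
    base = {
        "LA": (+Wh / 2.0, y_clav),
        "RA": (-Wh / 2.0, y_clav),
        "LL": (+0.2 * Wh, y_ll),
        "RL": (-0.2 * Wh, y_ll),
    }
    centroid = np.mean([base[e] for e in ("LA", "RA", "LL")], axis=0)

    layout = ElectrodeLayout(Wh=Wh, Wv=Wv, f=f)
    dh, dv = layout.step_cm
    for side in ("front", "back"):
        for pos, (kh, kv) in POSITION_STEPS.items():
            coords = {}
            anchors = {}
            for name, (ex, ey) in base.items():
                if name != "RL":
                    sx = np.sign(centroid[0] - ex) or 1.0
                    sy = np.sign(centroid[1] - ey) or 1.0
                    ex = ex + sx * kh * dh
                    ey = ey + sy * kv * dv
                anchors[name] = (float(ex), float(ey))
                coords[name] = _surface_voxel(geometry, ex, ey, side,
                                              name, pos)
            layout.electrodes[(side, pos)] = coords
            layout.anchors[(side, pos)] = anchors
    return layout


def _surface_voxel(geometry: TorsoGeometry, ex: float, ey: float,
                   side: str, name: str, pos: int):
    x, y, z = geometry.cell_centers()
    ix = int(np.argmin(np.abs(x - ex)))
    iy = int(np.argmin(np.abs(y - ey)))
    if abs(x[ix] - ex) > geometry.spacing or abs(y[iy] - ey) > geometry.spacing:
        raise ValueError(
            f"electrode {name} (position {pos}, {side}) at "
            f"({ex:.1f}, {ey:.1f}) cm falls outside the torso surface")
    column = geometry.body_mask[ix, iy, :]
    if not column.any():
        raise ValueError(
            f"electrode {name} (position {pos}, {side}) at "
            f"({ex:.1f}, {ey:.1f}) cm falls outside the torso surface")
    iz = int(np.max(np.nonzero(column)) if side == "front"
             else np.min(np.nonzero(column)))
    return (ix, iy, iz)
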