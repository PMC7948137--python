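"""Electrode geometry for the International 10-5 system.

The montage supplies everything the filters and the simulator need to know
about the recording cap: channel labels, 3-D positions on a best-fit head
sphere, along-scalp (geodesic) distances, the cap radius, and left-right
mirror pairing across the sagittal midline.

Axis convention (right-handed head coordinates): x toward the right
pre-auricular point, y toward the nasion, z up.  The sagittal midline is
the plane x = 0; mirroring negates x.

Distances are geodesic arc lengths on the best-fit sphere, not 3-D chords:
a 2-D Gaussian field "on the scalp" is naturally parameterized by
along-scalp distance, and the cap radius (maximal distance between any
electrode and Cz) is defined the same way.  The 120-channel montage
shipped with the package has its sphere radius calibrated once so that
this cap radius equals 14.7 cm.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Montage",
    "standard_105_montage",
    "scalp_distance",
    "cap_radius",
    "mirror_electrode",
    "mirror_label",
    "read_sfp",
    "write_sfp",
    "read_elc",
]

#: Relative tolerance for the "positions lie on the head sphere" invariant.
SPHERE_RTOL = 0.05

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)(h?)$", re.IGNORECASE)


@dataclass
class Montage:
    """Electrode labels and positions on a best-fit head sphere.

    Parameters
    ----------
    labels : list of str
        Unique channel names (10-5 nomenclature for the shipped cap).
    positions : array, shape (n_channels, 3)
        Cartesian coordinates in cm (x right, y nasion, z up).
    head_radius : float, optional
        Radius (cm) of the head sphere.  Fitted from the positions when
        omitted.
    center : array, shape (3,), optional
        Sphere center in the same frame; fitted when omitted (origin for
        montages too small to fit, i.e. fewer than 10 channels).
    """

    labels: list[str]
    positions: np.ndarray
    head_radius: float | None = None
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = [str(lab) for lab in self.labels]
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n_channels, 3) array")
        if len(self.labels) != len(self.positions):
            raise ValueError(
                f"{len(self.labels)} labels for {len(self.positions)} positions"
            )
        if len({lab.lower() for lab in self.labels}) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("montage positions must be finite")
        if self.center is None or self.head_radius is None:
            center, radius = _fit_sphere(self.positions)
            if self.center is None:
                self.center = center
            if self.head_radius is None:
                self.head_radius = radius
        self.center = np.asarray(self.center, dtype=float)
        self.head_radius = float(self.head_radius)
        radii = np.linalg.norm(self.positions - self.center, axis=1)
        if len(self.labels) >= 4 and self.head_radius > 0:
            off = np.abs(radii - self.head_radius) / self.head_radius
            if off.max() > SPHERE_RTOL:
                worst = self.labels[int(off.argmax())]
                raise ValueError(
                    f"electrode {worst} lies {off.max():.1%} off the head sphere "
                    f"(tolerance {SPHERE_RTOL:.0%})"
                )

    # -- lookups ---------------------------------------------------------
    def index(self, label: str) -> int:
        """Channel index of ``label`` (case-insensitive)."""
        lower = [lab.lower() for lab in self.labels]
        try:
            return lower.index(str(label).lower())
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def __contains__(self, label: str) -> bool:
        return str(label).lower() in (lab.lower() for lab in self.labels)

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def unit_vectors(self) -> np.ndarray:
        """Unit vectors from the sphere center to each electrode."""
        v = self.positions - self.center
        return v / np.linalg.norm(v, axis=1)[:, None]

    # -- geometry --------------------------------------------------------
    def scalp_distance(self, a: str, b: str) -> float:
        """Geodesic arc length (cm) between electrodes ``a`` and ``b``."""
        ia, ib = self.index(a), self.index(b)
        if ia == ib:
            return 0.0
        u = self.unit_vectors()
        cosang = float(np.clip(u[ia] @ u[ib], -1.0, 1.0))
        return self.head_radius * float(np.arccos(cosang))

    def scalp_distances_from(self, label: str) -> np.ndarray:
        """Geodesic distance (cm) from ``label`` to every electrode."""
        u = self.unit_vectors()
        cosang = np.clip(u @ u[self.index(label)], -1.0, 1.0)
        return self.head_radius * np.arccos(cosang)

    def cap_radius(self) -> float:
        """Maximal scalp distance between any electrode and Cz (cm)."""
        if "Cz" not in self:
            raise KeyError("cap radius is defined relative to Cz, which is missing")
        return float(self.scalp_distances_from("Cz").max())

    def mirror_electrode(self, label: str) -> str:
        """The electrode symmetrical to ``label`` across the sagittal midline.

        Pairing follows the 10-5 label grammar (odd digit <-> even digit,
        "z" labels map to themselves); geometry is validated by the test
        suite, not recomputed here.
        """
        idx = self.index(label)
        partner = mirror_label(self.labels[idx])
        if partner not in self:
            raise KeyError(
                f"mirror partner {partner!r} of {label!r} is absent from the montage"
            )
        return self.labels[self.index(partner)]

    def subset(self, labels: list[str]) -> "Montage":
        """A montage restricted to ``labels`` (same sphere)."""
        idx = [self.index(lab) for lab in labels]
        return Montage(
            [self.labels[i] for i in idx],
            self.positions[idx],
            head_radius=self.head_radius,
            center=self.center.copy(),
        )


def mirror_label(label: str) -> str:
    """Mirror partner of a 10-5 label under the sagittal-midline grammar.

    Odd digits map to the next even digit and vice versa (C3 <-> C4,
    P7 <-> P8, T9 <-> T10, FCC3h <-> FCC4h); "z"-suffixed labels are on
    the midline and map to themselves.
    """
    m = _LABEL_RE.match(str(label))
    if not m:
        raise ValueError(f"cannot parse electrode label {label!r} as 10-5")
    pre, num, h = m.groups()
    if num.lower() == "z":
        return str(label)
    n = int(num)
    return f"{pre}{n + 1 if n % 2 == 1 else n - 1}{h}"


def _fit_sphere(positions: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit; falls back to the origin for
    montages too small or degenerate to constrain a fit."""
    pos = np.asarray(positions, dtype=float)
    if len(pos) >= 10:
        design = np.c_[2 * pos, np.ones(len(pos))]
        rhs = (pos**2).sum(axis=1)
        sol, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
        if rank == 4:
            center = sol[:3]
            radius = float(np.sqrt(max(sol[3] + center @ center, 0.0)))
            if radius > 0:
                return center, radius
    center = np.zeros(3)
    radius = float(np.linalg.norm(pos, axis=1).max()) if len(pos) else 0.0
    return center, radius


# -- module-level operation aliases ------------------------------------------

def scalp_distance(montage: Montage, a: str, b: str) -> float:
    """Geodesic scalp distance (cm) between electrodes ``a`` and ``b``."""
    return montage.scalp_distance(a, b)


def cap_radius(montage: Montage) -> float:
    """Maximal scalp distance between any electrode and Cz (cm)."""
    return montage.cap_radius()


def mirror_electrode(montage: Montage, label: str) -> str:
    """Left-right mirror partner of ``label`` in ``montage``."""
    return montage.mirror_electrode(label)


# -- standard montage and file I/O -------------------------------------------

def standard_105_montage(n_channels: int = 120) -> Montage:
    """The 120-channel International 10-5 montage shipped with the package.

    Positions lie exactly on a head sphere whose radius is calibrated so
    that the cap radius (maximal geodesic distance from Cz) is 14.7 cm.

    Parameters
    ----------
    n_channels : int
        Cap size; only the 120-channel cap is shipped.
    """
    if int(n_channels) != 120:
        raise ValueError(
            f"no {n_channels}-channel 10-5 cap is shipped; supported sizes: 120"
        )
    with resources.files("lsafilter.data").joinpath(
        "standard_105_120ch.sfp"
    ).open("r") as fh:
        head_radius = None
        for line in fh:
            if line.startswith("# head_radius_cm"):
                head_radius = float(line.split()[-1])
            if not line.startswith("#"):
                break
        fh.seek(0)
        montage = read_sfp(fh, head_radius=head_radius, center=np.zeros(3))
    return montage


def read_sfp(path, unit: str = "cm", head_radius: float | None = None,
             center: np.ndarray | None = None) -> Montage:
    """Read electrode positions from a .sfp table (label, x, y, z).

    Lines starting with ``#`` are comments; fiducial rows (labels starting
    with ``fid``) are skipped.  ``unit`` declares the coordinate unit of
    the file (.sfp carries no unit metadata); positions are converted to cm.
    """
    scale = {"cm": 1.0, "mm": 0.1, "m": 100.0}[unit]
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    labels, rows = [], []
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed .sfp line {lineno}: {line!r}")
        if parts[0].lower().startswith("fid"):
            continue
        labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError:
            raise ValueError(f"non-numeric coordinate on .sfp line {lineno}: {line!r}")
    if not labels:
        raise ValueError("no electrode rows found in .sfp file")
    return Montage(labels, scale * np.array(rows), head_radius=head_radius,
                   center=center)


def write_sfp(montage: Montage, path, overwrite: bool = False) -> None:
    """Write a montage to a .sfp table in cm (label, x, y, z)."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with path.open("w") as fh:
        fh.write("# columns: label x y z (cm); x right, y nasion, z up\n")
        fh.write(f"# head_radius_cm {montage.head_radius:.6f}\n")
        for lab, (x, y, z) in zip(montage.labels, montage.positions):
            fh.write(f"{lab}\t{x:.5f}\t{y:.5f}\t{z:.5f}\n")


def read_elc(path) -> Montage:
    """Read electrode positions from an ASA-style .elc file.

    Delegates parsing to :func:`mne.channels.read_custom_montage` (which
    honors the file's ``UnitPosition`` declaration) and converts the
    positions to cm.
    """
    import mne

    custom = mne.channels.read_custom_montage(str(path), head_size=None)
    ch_pos = custom.get_positions()["ch_pos"]
    labels = list(ch_pos)
    positions = 100.0 * np.array([ch_pos[lab] for lab in labels])  # m -> cm
    return Montage(labels, positions)
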