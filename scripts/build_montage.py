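"""Regenerate the shipped 120-channel 10-5 montage table.

Maintenance script, not part of the installed package.  Takes the standard
10-5 electrode positions distributed with MNE-Python (Oostenveld layout),
projects them onto the best-fit head sphere, enforces exact left-right
mirror symmetry, and calibrates the sphere radius so that the maximal
geodesic distance from Cz (the "cap radius") equals 14.7 cm.  The result is
written to src/lsafilter/data/standard_105_120ch.sfp as a plain-text table
(label, x, y, z in cm; x toward the right ear, y toward the nasion, z up).

Run from the repository root:  python scripts/build_montage.py
"""
from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np

CAP_RADIUS_CM = 14.7

# Standard 10-10 cap (digits <= 8): midline plus mirror-closed lateral pairs.
TEN_TEN = [
    "Fpz", "AFz", "Fz", "FCz", "FCCz", "Cz", "CPz", "Pz", "POz", "Oz",
    "Fp1", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "PO4", "PO8",
    "O1", "O2",
]

# 10-5 intermediate ("h") electrodes named in the package documentation and
# examples; forced into the cap regardless of the angular fill order.
MUST_HAVE_H = ["FCC3h", "FCC4h", "FFC5h", "FFC6h"]

LABEL_RE = re.compile(r"^([A-Z]+?)(z|\d+)(h?)$", re.IGNORECASE)


def mirror_label(label: str) -> str:
    pre, num, h = LABEL_RE.match(label).groups()
    if num == "z":
        return label
    n = int(num)
    partner = n + 1 if n % 2 == 1 else n - 1
    return f"{pre}{partner}{h}"


def main() -> None:
    warnings.filterwarnings("ignore")
    import mne

    montage = mne.channels.make_standard_montage("standard_1005")
    ch_pos = montage.get_positions()["ch_pos"]
    labels = list(ch_pos)
    pos = np.array([ch_pos[lab] for lab in labels])

    # Algebraic best-fit sphere over the full 10-5 set (stable, unlike a fit
    # restricted to the upper cap).
    design = np.c_[2 * pos, np.ones(len(pos))]
    sol, *_ = np.linalg.lstsq(design, (pos**2).sum(axis=1), rcond=None)
    center = sol[:3]
    unit = pos - center
    unit /= np.linalg.norm(unit, axis=1)[:, None]
    upos = dict(zip(labels, unit))

    angle_from_cz = {
        lab: float(np.arccos(np.clip(u @ upos["Cz"], -1.0, 1.0)))
        for lab, u in upos.items()
    }

    selected = list(TEN_TEN) + list(MUST_HAVE_H)
    h_candidates = sorted(
        (
            lab
            for lab in labels
            if LABEL_RE.match(lab)
            and lab.endswith("h")
            and lab not in selected
            and LABEL_RE.match(lab).group(2) != "z"
            and int(LABEL_RE.match(lab).group(2)) <= 8
            and mirror_label(lab) in labels
        ),
        key=lambda lab: (angle_from_cz[lab], lab),
    )
    for lab in h_candidates:
        if len(selected) >= 120:
            break
        partner = mirror_label(lab)
        if lab in selected or partner in selected:
            continue
        if len(selected) > 118:  # only a midline slot would fit
            continue
        selected.extend([lab, partner])
    assert len(selected) == 120, len(selected)

    # Exact mirror symmetry: average each pair with its reflection; pin the
    # midline to the sagittal plane x = 0.
    sym = {}
    for lab in selected:
        u = upos[lab].copy()
        partner = mirror_label(lab)
        if partner == lab:
            u[0] = 0.0
        else:
            u = 0.5 * (u + upos[partner] * np.array([-1.0, 1.0, 1.0]))
        sym[lab] = u / np.linalg.norm(u)

    theta_max = max(
        np.arccos(np.clip(sym[lab] @ sym["Cz"], -1.0, 1.0)) for lab in selected
    )
    radius = CAP_RADIUS_CM / theta_max
    print(f"theta_max = {np.degrees(theta_max):.2f} deg -> head radius {radius:.4f} cm")

    out = Path(__file__).resolve().parents[1] / "src/lsafilter/data/standard_105_120ch.sfp"
    with out.open("w") as fh:
        fh.write(f"# 120-channel International 10-5 montage on a head sphere\n")
        fh.write(f"# columns: label x y z (cm); x right, y nasion, z up\n")
        fh.write(f"# head_radius_cm {radius:.6f}\n")
        for lab in selected:
            x, y, z = radius * sym[lab]
            fh.write(f"{lab}\t{x:.5f}\t{y:.5f}\t{z:.5f}\n")
    print(f"wrote {out} ({len(selected)} channels)")


if __name__ == "__main__":
    main()
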