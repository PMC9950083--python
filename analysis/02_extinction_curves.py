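#!/usr/bin/env python
"""Extinction efficiencies of dome- and semi-capsule-shaped scatterers.

Computes Q_ext(nu) for a non-absorbing (n = 1.5) dome of radius 10 um
elongated into semi-capsules (L = 0 .. 500 um), the infinite
semi-cylinder limit, and the exact-Mie sphere reference.  Writes the
curve table and a wiggle-position table to results/ and prints the two
findings: the wiggle structure shifts to lower wavenumbers with
elongation, and the semi-capsule approaches the semi-cylinder.
"""

import numpy as np
import pandas as pd

from domescatter.extinction import (
    first_wiggle_maximum,
    qext_mie_exact,
    qext_semicapsule,
    qext_semicylinder,
    qext_vdh_sphere,
)
from domescatter.refindex import default_grid

R = 10.0
ELONGATIONS = [0.0, 2.5, 5.0, 10.0, 15.0, 30.0, 500.0]


def main() -> None:
    grid = default_grid(1000, 6000, 10.0)

    table = {"wavenumber_cm-1": grid}
    for L in ELONGATIONS:
        table[f"capsule_L{L:g}"] = qext_semicapsule(1.5, R, L, grid).qext
    qcyl = qext_semicylinder(1.5, R, grid).qext
    table["semicylinder"] = qcyl
    table["sphere_mie"] = qext_mie_exact(1.5, R, grid).qext
    table["sphere_vdh"] = qext_vdh_sphere(1.5, R, grid).qext
    pd.DataFrame(table).to_csv("results/extinction_curves.csv", index=False,
                               float_format="%.8g")

    g_wiggle = default_grid(800, 3000, 2.0)
    rows = []
    for L in ELONGATIONS[:5]:
        q = qext_semicapsule(1.5, R, L, g_wiggle).qext
        rows.append({"L_um": L, "first_wiggle_max_cm-1":
                     round(first_wiggle_maximum(g_wiggle, q), 1)})
    wiggles = pd.DataFrame(rows)
    wiggles.to_csv("results/wiggle_positions.csv", index=False)

    print("first wiggle maximum vs elongation (R = 10 um, n = 1.5):")
    print(wiggles.to_string(index=False))
    drop = wiggles["first_wiggle_max_cm-1"].iloc[0] - wiggles["first_wiggle_max_cm-1"].iloc[-1]
    print(f"-> elongation L = 0 -> 15 um shifts the first wiggle down by {drop:.0f} cm^-1")

    gap = np.max(np.abs(table["capsule_L500"] - qcyl)) / np.max(qcyl)
    print(f"-> at L = 500 um the capsule curve is within {100 * gap:.2f}% of the "
          "infinite semi-cylinder")
    print("wrote results/extinction_curves.csv and results/wiggle_positions.csv")


if __name__ == "__main__":
    main()
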