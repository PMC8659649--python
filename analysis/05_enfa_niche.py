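#!/usr/bin/env python
"""ENFA niche description of the focal species.

Contrasts the environment at presence cells with the whole landscape:
the marginality vector says which covariates displace the niche barycentre
from the average available conditions (and in which direction), the
specialization eigenvalues say how much narrower than the landscape the
occupied environmental space is.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tsetse_sdm import enfa_design_matrix, enfa_fit, standardize_global
from tsetse_sdm.stack import CovariateStack

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "survey"
RESULTS = ROOT / "results"


def main() -> None:
    stack = CovariateStack.from_dir(SCRATCH / "stack")
    design = pd.read_csv(SCRATCH / "design.csv")
    pres = design[design["role"] == "presence"]
    matrix, names = enfa_design_matrix(stack)
    z, _ = standardize_global(matrix, names)
    valid = stack.valid_indices()
    row, col = stack.grid.cell_of(pres["x"].to_numpy(), pres["y"].to_numpy())
    idx = np.searchsorted(valid, np.asarray(stack.grid.flat_index(row, col)))
    result = enfa_fit(z, idx, names=names)

    result.to_csv(RESULTS / "05_enfa_loadings.csv")
    summary = pd.DataFrame(
        {
            "covariate": names,
            "marginality_sd_units": np.round(result.marginality_vector, 3),
            "marginality_pct": np.round(result.marginality_percent().to_numpy(), 1),
        }
    ).sort_values("marginality_pct", ascending=False)
    summary.to_csv(RESULTS / "05_enfa_marginality.csv", index=False)
    print(summary.to_string(index=False))
    print(
        f"\nmarginality index {result.marginality_index:.3f} "
        f"(1 ~ niche barycentre at the available space's 97.5% bound); "
        f"global specialization {result.global_specialization:.3f}; "
        f"leading specialization eigenvalues "
        f"{np.round(result.specialization_eigenvalues[:3], 2).tolist()}"
    )


if __name__ == "__main__":
    main()
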