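"""Presence calling: occupancy-thresholded detection per (phenotype, compartment).

A lipid variable is called *present* in a group when a strict majority of
that group's samples detect it: signal strength > 0 in at least 66% of the
samples (so 6/8 passes, 5/8 does not, and 2/3 = 0.667 passes).  Occupancy
fractions are retained alongside the boolean calls for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .dataio import AbundanceTable, DataValidationError, StudyDesign

__all__ = ["PresenceMatrix", "call_presence", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.66


@dataclass
class PresenceMatrix:
    """Presence calls over (phenotype, compartment) groups x variables.

    Both frames share a two-level row index (phenotype, compartment) and one
    column per variable: ``occupancy`` holds the detection fraction in
    [0, 1], ``present`` the thresholded boolean call.
    """

    occupancy: pd.DataFrame
    present: pd.DataFrame
    threshold: float

    @property
    def phenotypes(self) -> list[str]:
        return sorted(self.occupancy.index.get_level_values(0).unique())

    @property
    def compartments(self) -> list[str]:
        return sorted(self.occupancy.index.get_level_values(1).unique())

    @property
    def variables(self) -> list[str]:
        return list(self.occupancy.columns)

    def pattern(self, phenotype: str, variable: str) -> frozenset[str]:
        """Set of compartments where ``variable`` is present for ``phenotype``."""
        calls = self.present.xs(phenotype, level=0)[variable]
        return frozenset(calls.index[calls])

    def to_long(self) -> pd.DataFrame:
        """Long-format audit table: phenotype, compartment, variable, occupancy, present."""
        occ = self.occupancy.stack()
        pres = self.present.stack()
        out = pd.DataFrame({"occupancy": occ, "present": pres})
        out.index.names = ["phenotype", "compartment", "variable"]
        return out.reset_index()

    def write_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False, float_format="%.6f")


def call_presence(
    table: AbundanceTable,
    design: StudyDesign,
    threshold: float = DEFAULT_THRESHOLD,
) -> PresenceMatrix:
    """Call presence per (phenotype, compartment) group and variable.

    Occupancy = (# samples with signal > 0) / (group size); missing values
    count as not detected but still count toward the group size.  Present
    iff occupancy >= ``threshold``.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    detected = table.detected()
    rows_occ = {}
    for p in design.phenotypes:
        for c in design.compartments:
            samples = design.samples_in(p, c)
            if not samples:
                continue
            missing = [s for s in samples if s not in detected.index]
            if missing:
                raise DataValidationError(
                    f"group ({p}, {c}) references samples absent from table: {missing}"
                )
            rows_occ[(p, c)] = detected.loc[samples].sum(axis=0) / len(samples)
    if not rows_occ:
        raise DataValidationError("design defines no non-empty (phenotype, compartment) group")
    occupancy = pd.DataFrame(rows_occ).T.sort_index()
    occupancy.index = pd.MultiIndex.from_tuples(
        occupancy.index, names=["phenotype", "compartment"]
    )
    present = occupancy.ge(threshold)
    return PresenceMatrix(occupancy, present, threshold)
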