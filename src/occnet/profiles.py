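"""Module presence profiles along the flow path.

For each network module and each sampling core, the presence fraction of a
member fragment is the share of that core's samples containing the fragment
(0 = absent from every core sample, 1 = present in all); the module mean is
the arithmetic mean of its member fragments' fractions. Plotted radially per
module, these profiles reveal which cores along the contaminant plume a
module's community occupies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .data import CORES, PresenceAbsenceMatrix, SampleMetadata, ValidationError
from .topology import ModulePartition

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ModuleProfile:
    """Long-format per-fragment fractions and per-module means by core."""

    fractions: pd.DataFrame  # columns: module, core, fragment, fraction
    module_means: pd.DataFrame  # columns: module, core, mean_fraction

    def mean(self, module, core: str) -> float:
        sel = self.module_means[
            (self.module_means["module"] == module) & (self.module_means["core"] == core)
        ]
        return float(sel["mean_fraction"].iloc[0])


def module_core_profile(
    m: PresenceAbsenceMatrix,
    metadata: Mapping[str, SampleMetadata],
    partition: ModulePartition | Mapping[str, int],
) -> ModuleProfile:
    """Per-core presence fractions for each module fragment and module means.

    Fragments of the matrix that are not in the partition are pooled into the
    pseudo-module "unassigned". Cores are reported in flow-path order
    (C1, C2, C3, C5, C8); cores with zero samples are excluded with a warning.
    """
    membership = partition.membership if isinstance(partition, ModulePartition) else dict(partition)
    missing = [s for s in m.sample_ids if s not in metadata]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:10]}")
    core_samples: dict[str, list[int]] = {c: [] for c in CORES}
    for idx, s in enumerate(m.sample_ids):
        core_samples[metadata[s].core].append(idx)
    empty = [c for c in CORES if not core_samples[c]]
    if empty:
        warnings.warn(f"cores with no samples excluded from profile: {empty}")
    cores = [c for c in CORES if core_samples[c]]

    rows = []
    for fi, frag in enumerate(m.fragment_ids):
        module = membership.get(frag, UNASSIGNED)
        for core in cores:
            cols = core_samples[core]
            frac = float(m.values[fi, cols].sum()) / len(cols)
            rows.append({"module": module, "core": core, "fragment": frag, "fraction": frac})
    fractions = pd.DataFrame(rows, columns=["module", "core", "fragment", "fraction"])
    module_means = (
        fractions.groupby(["module", "core"], sort=False)["fraction"]
        .mean()
        .reset_index()
        .rename(columns={"fraction": "mean_fraction"})
    )
    return ModuleProfile(fractions=fractions, module_means=module_means)
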