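"""Module schemes for cerebro-cerebellar network parcellations.

A *module* is one functional network restricted to one structure (cerebrum
or cerebellum) and one hemisphere. Two schemes are supported:

* ``seven``: 7 networks x 2 structures x 2 hemispheres = 28 modules.
* ``seventeen``: 17 networks x 2 structures x 2 hemispheres, minus the
  cerebellar VN A module (too few voxels in the reference cerebellar
  parcellation) = 34 cerebral + 32 cerebellar = 66 modules.

Hemispheres are coded relative to the lesion: *ipsilesional* (IL) and
*contralesional* (CL). Subjects with a right-hemisphere lesion are
standardised by swapping hemisphere labels (:func:`flip_hemispheres`), so IL
always corresponds to anatomical left after standardisation; controls use
left = IL by convention so group matrices align.

Matrix ordering is fixed and documented: cerebrum before cerebellum; within
each structure the IL block then the CL block; within each block, networks
in the canonical listing order below. The ordering is a convention of this
package chosen for reproducibility of serialised matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "SEVEN_NETWORKS",
    "SEVENTEEN_NETWORKS",
    "Structure",
    "Hemisphere",
    "EdgeFamily",
    "ModuleDef",
    "ModuleScheme",
    "build_scheme",
    "classify_edge",
    "flip_hemispheres",
]

#: Canonical network names for the coarse parcellation, in listing order.
SEVEN_NETWORKS: tuple[str, ...] = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")

#: Canonical network names for the fine parcellation, in listing order.
SEVENTEEN_NETWORKS: tuple[str, ...] = (
    "VN A", "VN B", "SMN A", "SMN B", "DAN A", "DAN B", "VAN A", "VAN B",
    "LN A", "LN B", "FPN C", "FPN A", "FPN B", "TPN", "DMN C", "DMN A",
    "DMN B",
)

#: Cerebellar networks excluded per scheme (VN A has too few voxels in the
#: cerebellar parcellation under the fine scheme).
_CEREBELLAR_EXCLUSIONS: dict[str, frozenset[str]] = {
    "seven": frozenset(),
    "seventeen": frozenset({"VN A"}),
}


class Structure(str, Enum):
    CEREBRUM = "cerebrum"
    CEREBELLUM = "cerebellum"


class Hemisphere(str, Enum):
    IPSI = "ipsilesional"
    CONTRA = "contralesional"

    @property
    def other(self) -> "Hemisphere":
        return Hemisphere.CONTRA if self is Hemisphere.IPSI else Hemisphere.IPSI


class EdgeFamily(str, Enum):
    """Taxonomy of unordered module pairs used to summarise group results.

    ``cbl_*`` families are cerebro-cerebellar; the ``contra``/``ipsi`` part
    names the cerebellar hemisphere relative to the cerebral module's
    hemisphere (the classical crossed cerebro-cerebellar circuit links a
    cerebral hemisphere to the *contralateral* cerebellum).
    """

    CEREBRAL_INTRA_IL = "cerebral_intra_IL"
    CEREBRAL_INTRA_CL = "cerebral_intra_CL"
    CEREBRAL_INTER = "cerebral_inter"
    CEREBELLAR_INTRA_IL = "cerebellar_intra_IL"
    CEREBELLAR_INTRA_CL = "cerebellar_intra_CL"
    CEREBELLAR_INTER = "cerebellar_inter"
    CBL_IL_TO_CONTRA_CBLM = "cbl_IL_to_contra_cblm"
    CBL_IL_TO_IPSI_CBLM = "cbl_IL_to_ipsi_cblm"
    CBL_CL_TO_CONTRA_CBLM = "cbl_CL_to_contra_cblm"
    CBL_CL_TO_IPSI_CBLM = "cbl_CL_to_ipsi_cblm"


@dataclass(frozen=True)
class ModuleDef:
    """One module: a network within one structure and one hemisphere."""

    network: str
    structure: Structure
    hemisphere: Hemisphere
    index: int

    @property
    def name(self) -> str:
        hemi = "IL" if self.hemisphere is Hemisphere.IPSI else "CL"
        struct = "Ce" if self.structure is Structure.CEREBRUM else "Cb"
        return f"{struct}-{hemi}-{self.network}"


@dataclass(frozen=True)
class ModuleScheme:
    """An ordered set of modules defining matrix order and edge families."""

    condition: str
    modules: tuple[ModuleDef, ...]

    def __post_init__(self) -> None:
        indices = [m.index for m in self.modules]
        if indices != list(range(len(self.modules))):
            raise ValueError("module indices must be 0..M-1 in order")

    @property
    def total_count(self) -> int:
        return len(self.modules)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.modules]

    def count(self, structure: Structure) -> int:
        return sum(m.structure is structure for m in self.modules)

    def edges(self) -> Iterable[tuple[int, int]]:
        """All unordered module pairs (i < j) in row-major order."""
        return itertools.combinations(range(self.total_count), 2)

    @property
    def n_edges(self) -> int:
        m = self.total_count
        return m * (m - 1) // 2

    def mirror_permutation(self) -> list[int]:
        """Index permutation mapping each module to its opposite-hemisphere
        twin (same network, same structure)."""
        lookup = {
            (m.network, m.structure, m.hemisphere): m.index for m in self.modules
        }
        return [
            lookup[(m.network, m.structure, m.hemisphere.other)]
            for m in self.modules
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [m.index for m in self.modules],
                "network": [m.network for m in self.modules],
                "structure": [m.structure.value for m in self.modules],
                "hemisphere": [m.hemisphere.value for m in self.modules],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, condition: str = "custom") -> "ModuleScheme":
        df = pd.read_csv(path, sep="\t").sort_values("index")
        mods = tuple(
            ModuleDef(
                network=row["network"],
                structure=Structure(row["structure"]),
                hemisphere=Hemisphere(row["hemisphere"]),
                index=int(row["index"]),
            )
            for row in df.to_dict("records")
        )
        return cls(condition=condition, modules=mods)


def build_scheme(condition: str) -> ModuleScheme:
    """Build the 28-module (``seven``) or 66-module (``seventeen``) scheme.

    Ordering: cerebrum then cerebellum; within each structure the
    ipsilesional block then the contralesional block; within each block the
    networks in canonical listing order, skipping excluded cerebellar
    networks.
    """
    if condition not in ("seven", "seventeen"):
        raise ValueError(f"condition must be 'seven' or 'seventeen', got {condition!r}")
    networks = SEVEN_NETWORKS if condition == "seven" else SEVENTEEN_NETWORKS
    excluded = _CEREBELLAR_EXCLUSIONS[condition]
    modules: list[ModuleDef] = []
    for structure in (Structure.CEREBRUM, Structure.CEREBELLUM):
        for hemisphere in (Hemisphere.IPSI, Hemisphere.CONTRA):
            for network in networks:
                if structure is Structure.CEREBELLUM and network in excluded:
                    continue
                modules.append(
                    ModuleDef(network, structure, hemisphere, index=len(modules))
                )
    return ModuleScheme(condition=condition, modules=tuple(modules))


def classify_edge(scheme: ModuleScheme, i: int, j: int) -> EdgeFamily:
    """Assign the unordered pair (i, j) to its edge family.

    Symmetric in (i, j). Raises ``ValueError`` for self-edges or indices
    outside the scheme.
    """
    m = scheme.total_count
    if not (0 <= i < m and 0 <= j < m):
        raise ValueError(f"module indices must be in [0, {m}), got ({i}, {j})")
    if i == j:
        raise ValueError("self-edges have no family")
    a, b = scheme.modules[i], scheme.modules[j]
    if a.structure is b.structure:
        prefix = "cerebral" if a.structure is Structure.CEREBRUM else "cerebellar"
        if a.hemisphere is b.hemisphere:
            side = "IL" if a.hemisphere is Hemisphere.IPSI else "CL"
            return EdgeFamily(f"{prefix}_intra_{side}")
        return EdgeFamily(f"{prefix}_inter")
    cerebral = a if a.structure is Structure.CEREBRUM else b
    cerebellar = b if a.structure is Structure.CEREBRUM else a
    side = "IL" if cerebral.hemisphere is Hemisphere.IPSI else "CL"
    rel = "ipsi" if cerebellar.hemisphere is cerebral.hemisphere else "contra"
    return EdgeFamily(f"cbl_{side}_to_{rel}_cblm")


def edge_families(scheme: ModuleScheme) -> list[EdgeFamily]:
    """Family of every unordered edge, in `scheme.edges()` order."""
    return [classify_edge(scheme, i, j) for i, j in scheme.edges()]


def flip_hemispheres(record, scheme: ModuleScheme):
    """Standardise a subject so the ipsilesional hemisphere is the IL block.

    For a subject with a right-hemisphere lesion the module time-series
    columns are swapped with their opposite-hemisphere twins (the
    module-level equivalent of flipping the image left-right under a
    hemisphere-symmetric atlas). Left-lesion subjects and controls are
    returned unchanged. The operation is an involution.
    """
    if record.lesion_hemisphere != "right":
        return record
    perm = scheme.mirror_permutation()
    ts = record.module_ts
    flipped = ts.iloc[:, perm].copy()
    flipped.columns = ts.columns
    return replace(record, module_ts=flipped)
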