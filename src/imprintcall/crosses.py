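"""Cross designs for reciprocal and triparental imprinting studies.

A cross direction is described by the founder inbred lines contributing the
maternal and the paternal genome, plus the tissue assayed.  Under biallelic
expression the expected maternal transcript fraction follows ploidy: 1/2 in
the diploid embryo and 2/3 in the triploid endosperm, which carries two
maternal genome copies and one paternal copy.

The default design mirrors a triparental study in maize: the B73 x Mo17 (or
Mo17 x B73) F1 hybrid crossed reciprocally with an inducer line CAU5
(pairs ``BM-C/C-BM`` and ``MB-C/C-MB``), alongside the two-parent reciprocal
pairs ``BC/CB`` (B73 vs CAU5) and ``MC/CM`` (Mo17 vs CAU5), each assayed in
embryo and endosperm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

EMBRYO = "embryo"
ENDOSPERM = "endosperm"
TISSUES = (EMBRYO, ENDOSPERM)

B73 = "B73"
MO17 = "Mo17"
CAU5 = "CAU5"


def expected_maternal_fraction(tissue: str) -> float:
    """Null maternal transcript fraction for a tissue (1/2 embryo, 2/3 endosperm)."""
    if tissue == EMBRYO:
        return 0.5
    if tissue == ENDOSPERM:
        return 2.0 / 3.0
    raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")


@dataclass(frozen=True)
class CrossSpec:
    """One cross direction: who is the mother, who is the father, which tissue."""

    name: str
    maternal_founders: frozenset[str]
    paternal_founders: frozenset[str]
    tissue: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "maternal_founders", frozenset(self.maternal_founders))
        object.__setattr__(self, "paternal_founders", frozenset(self.paternal_founders))
        if not self.maternal_founders or not self.paternal_founders:
            raise ValueError(f"cross {self.name!r}: founder sets must be non-empty")
        if self.maternal_founders & self.paternal_founders:
            raise ValueError(
                f"cross {self.name!r}: maternal and paternal founder sets overlap"
            )
        expected_maternal_fraction(self.tissue)  # validates the tissue name

    @property
    def expected_maternal_fraction(self) -> float:
        return expected_maternal_fraction(self.tissue)

    @property
    def sample_id(self) -> str:
        return f"{self.name}.{self.tissue}"

    def reciprocal(self, name: str) -> "CrossSpec":
        """The same founders with maternal/paternal roles exchanged."""
        return CrossSpec(
            name=name,
            maternal_founders=self.paternal_founders,
            paternal_founders=self.maternal_founders,
            tissue=self.tissue,
        )


@dataclass(frozen=True)
class ReciprocalPair:
    """The two directions of one reciprocal cross, in one tissue."""

    name: str
    direction1: CrossSpec
    direction2: CrossSpec

    def __post_init__(self) -> None:
        d1, d2 = self.direction1, self.direction2
        if d1.tissue != d2.tissue:
            raise ValueError(f"pair {self.name!r}: directions assay different tissues")
        if (
            d1.maternal_founders != d2.paternal_founders
            or d1.paternal_founders != d2.maternal_founders
        ):
            raise ValueError(f"pair {self.name!r}: directions are not reciprocal")

    @property
    def tissue(self) -> str:
        return self.direction1.tissue

    @property
    def directions(self) -> tuple[CrossSpec, CrossSpec]:
        return (self.direction1, self.direction2)


_DEFAULT_PAIRS: tuple[tuple[str, tuple[str, str], frozenset, frozenset], ...] = (
    ("BM-C/C-BM", ("BM-C", "C-BM"), frozenset({B73, MO17}), frozenset({CAU5})),
    ("MB-C/C-MB", ("MB-C", "C-MB"), frozenset({B73, MO17}), frozenset({CAU5})),
    ("BC/CB", ("BC", "CB"), frozenset({B73}), frozenset({CAU5})),
    ("MC/CM", ("MC", "CM"), frozenset({MO17}), frozenset({CAU5})),
)


def make_pair(
    name: str,
    direction_names: tuple[str, str],
    maternal: Iterable[str],
    paternal: Iterable[str],
    tissue: str,
) -> ReciprocalPair:
    d1 = CrossSpec(direction_names[0], frozenset(maternal), frozenset(paternal), tissue)
    d2 = d1.reciprocal(direction_names[1])
    return ReciprocalPair(name=name, direction1=d1, direction2=d2)


def default_design(tissues: Sequence[str] = TISSUES) -> list[ReciprocalPair]:
    """Four reciprocal pairs (BM-C/C-BM, MB-C/C-MB, BC/CB, MC/CM) per tissue."""
    design = []
    for tissue in tissues:
        for name, dnames, mat, pat in _DEFAULT_PAIRS:
            design.append(make_pair(name, dnames, mat, pat, tissue))
    return design


def samples(design: Sequence[ReciprocalPair]) -> list[CrossSpec]:
    """Flatten a design into its individual cross-direction samples."""
    return [d for pair in design for d in pair.directions]


def write_cross_config(design: Sequence[ReciprocalPair], path: str | Path) -> None:
    """Serialise a design to YAML (pairs collapsed over tissues)."""
    seen: dict[str, dict] = {}
    for pair in design:
        entry = seen.setdefault(
            pair.name,
            {
                "name": pair.name,
                "direction_names": [pair.direction1.name, pair.direction2.name],
                "maternal": sorted(pair.direction1.maternal_founders),
                "paternal": sorted(pair.direction1.paternal_founders),
                "tissues": [],
            },
        )
        if pair.tissue not in entry["tissues"]:
            entry["tissues"].append(pair.tissue)
    with open(path, "w") as fh:
        yaml.safe_dump({"pairs": list(seen.values())}, fh, sort_keys=True)


def load_cross_config(path: str | Path) -> list[ReciprocalPair]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    design = []
    for entry in doc["pairs"]:
        for tissue in entry["tissues"]:
            design.append(
                make_pair(
                    entry["name"],
                    tuple(entry["direction_names"]),
                    entry["maternal"],
                    entry["paternal"],
                    tissue,
                )
            )
    return design
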