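"""Bundled reference data: gene panels, chemical annotations, study designs.

The 26 reference chemicals and their genotoxicity classification, the
12-gene and 4-gene marker panels, and the dose-group availability of each
chemical at the two sampling times are shipped as package resources so the
whole pipeline runs without any external download.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .errors import DomainError
from .types import (
    ChemClass,
    ChemicalAnnotation,
    DoseLevel,
    GenePanel,
    TimePoint,
    dose_point_id,
)

FOUR_GENES = ("Bax", "Btg2", "Ccng1", "Cdkn1a")

#: Abbreviations of the three chemicals with contradictory genotoxicity
#: evidence (Salmonella-negative, in vivo liver positive).
INTERMEDIATE_CHEMICALS = ("MP", "MCT", "TAA")


def _read_resource(name: str) -> pd.DataFrame:
    with resources.files("genotoxpca.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


@lru_cache(maxsize=None)
def builtin_panel(name: str) -> GenePanel:
    """Return a bundled marker panel: ``FOUR`` or ``TWELVE``.

    ``FOUR`` is the consensus panel (Bax, Btg2, Ccng1, Cdkn1a) shared
    between the JEMS/MMS 12-gene set and the US EPA 7-gene set; ``TWELVE``
    is the full JEMS/MMS set.
    """
    key = str(name).strip().upper()
    table = _read_resource("panels.tsv")
    gene_ids = dict(zip(table["symbol"], table["gene_id"].astype(int)))
    if key == "TWELVE":
        genes = tuple(table["symbol"])
    elif key == "FOUR":
        genes = FOUR_GENES
    else:
        raise DomainError(f"unknown panel name: {name!r} (expected FOUR or TWELVE)")
    return GenePanel(
        name=key, genes=genes, gene_ids={g: gene_ids[g] for g in genes}
    )


@lru_cache(maxsize=None)
def builtin_annotations() -> tuple[ChemicalAnnotation, ...]:
    """The 26 reference chemicals with class labels and assay evidence."""
    table = _read_resource("chemicals.tsv")
    out = []
    for rec in table.to_dict("records"):
        out.append(
            ChemicalAnnotation(
                name=rec["name"],
                abbreviation=rec["abbreviation"],
                class_label=ChemClass(rec["class"]),
                cas=rec["cas"],
                evidence={
                    "salmonella": str(rec["salmonella"]),
                    "in_vivo_liver": str(rec["in_vivo_liver"]),
                    "liver_carcinogen": str(rec["liver_carcinogen"]),
                    "iarc_group": str(rec["iarc_group"]),
                },
            )
        )
    return tuple(out)


@lru_cache(maxsize=None)
def annotation_map() -> dict[str, ChemicalAnnotation]:
    return {a.abbreviation: a for a in builtin_annotations()}


def class_of(abbreviation: str) -> ChemClass:
    try:
        return annotation_map()[abbreviation].class_label
    except KeyError:
        raise DomainError(f"unknown chemical abbreviation: {abbreviation!r}")


# Dose groups absent from the public database at 29 days of repeated dosing.
# All 26 chemicals have low/middle/high at 24 h.
_MISSING_29D: dict[str, tuple[DoseLevel, ...]] = {
    "AFL": (DoseLevel.LOW, DoseLevel.MIDDLE, DoseLevel.HIGH),
    "2NF": (DoseLevel.LOW, DoseLevel.MIDDLE, DoseLevel.HIGH),
    "NNM": (DoseLevel.LOW, DoseLevel.MIDDLE, DoseLevel.HIGH),
    "DEX": (DoseLevel.LOW, DoseLevel.MIDDLE, DoseLevel.HIGH),
    "DEN": (DoseLevel.HIGH,),
    "IND": (DoseLevel.HIGH,),
    "MCT": (DoseLevel.HIGH,),
}

_TREATED_DOSES = (DoseLevel.LOW, DoseLevel.MIDDLE, DoseLevel.HIGH)


def available_doses(chemical: str, time_point: TimePoint) -> tuple[DoseLevel, ...]:
    """Treated dose levels available for *chemical* at *time_point*."""
    if time_point is TimePoint.SINGLE_24H:
        return _TREATED_DOSES
    missing = _MISSING_29D.get(chemical, ())
    return tuple(d for d in _TREATED_DOSES if d not in missing)


def study_design(
    time_point: TimePoint,
    include_intermediates: bool = False,
) -> pd.DataFrame:
    """Enumerate the dose points of one reference analysis.

    Returns a frame with columns ``dose_point``, ``chemical``, ``dose``,
    ``class`` — one row per (chemical, treated dose) available at
    *time_point*. Intermediate chemicals are appended only on request, as
    they form the query set rather than the labeled reference set.
    """
    time_point = TimePoint(time_point)
    rows = []
    for ann in builtin_annotations():
        if ann.class_label is ChemClass.INTERMEDIATE and not include_intermediates:
            continue
        for dose in available_doses(ann.abbreviation, time_point):
            rows.append(
                {
                    "dose_point": dose_point_id(ann.abbreviation, dose, time_point),
                    "chemical": ann.abbreviation,
                    "dose": dose,
                    "class": ann.class_label,
                }
            )
    return pd.DataFrame(rows)


def design_labels(design: pd.DataFrame) -> pd.Series:
    """Class label per dose point, indexed by dose-point id."""
    return pd.Series(
        design["class"].to_numpy(), index=pd.Index(design["dose_point"]), name="class"
    )


def labels_for_rows(rows, time_point: TimePoint | None = None) -> pd.Series:
    """Infer class labels for dose-point row ids via the bundled annotations."""
    from .types import parse_dose_point

    out = {}
    for r in rows:
        chem, _, _ = parse_dose_point(r, default_time=time_point)
        out[r] = class_of(chem)
    return pd.Series(out, name="class")
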