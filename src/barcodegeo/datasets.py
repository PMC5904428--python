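"""Access to the packaged specimen table of the published survey.

The package ships the printed specimen metadata (IDs, taxa, decimal-degree
coordinates, bioregion codes) for the 97 ingroup and 21 outgroup specimens.
Sequences are *not* shipped; the GenBank/BOLD accessions are documented in
the README and retrieval is left to the user.
"""

from __future__ import annotations

from importlib import resources

from .alignment_io import SpecimenRecord, read_metadata

__all__ = ["study_specimen_metadata", "study_ingroup_metadata"]

INGROUP_TAXON = "Glomeris marginata"


def _data_path(name: str):
    return resources.files("barcodegeo.data").joinpath(name)


def study_specimen_metadata() -> list[SpecimenRecord]:
    """All 118 specimen records (97 ingroup with coordinates, 21 outgroup)."""
    with resources.as_file(_data_path("specimens_glomeris.tsv")) as path:
        return read_metadata(path)


def study_ingroup_metadata() -> list[SpecimenRecord]:
    """The 97 ingroup records, each with coordinates and a bioregion."""
    return [m for m in study_specimen_metadata() if m.taxon == INGROUP_TAXON]
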