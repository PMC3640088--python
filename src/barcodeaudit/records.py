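"""Core domain types: specimen records, taxonomy index, dataset container.

A :class:`SpecimenRecord` ties a vouchered herbarium collection to its DNA
barcode sequence, taxonomic determination and amplification outcome.  A
:class:`Dataset` is an ordered collection of records plus a genus → family →
order lookup used for severity classification of barcode errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

#: Rank/uncertainty markers stripped when parsing a genus or binomial from a
#: taxon name ("Russula cf. fragilis" → genus "Russula", binomial
#: "Russula fragilis").
RANK_MARKERS = {"cf.", "aff.", "cf", "aff", "sp.", "sp"}

#: Infraspecific rank connectors; everything from the connector onward is
#: dropped when collapsing a name to its binomial.
INFRASPECIFIC_MARKERS = {"var.", "var", "f.", "fo.", "forma", "subsp.", "ssp.", "subsp", "ssp"}


def _tokens(taxon_name: str) -> list[str]:
    return [t for t in taxon_name.split() if t not in RANK_MARKERS]


def parse_genus(taxon_name: str) -> str:
    """First whitespace token of *taxon_name* after stripping rank markers."""
    toks = _tokens(taxon_name)
    return toks[0] if toks else ""


def binomial(taxon_name: str, collapse_infraspecific: bool = True) -> str:
    """Collapse a taxon name to its binomial (genus + epithet).

    Infraspecific epithets (var., f., subsp.) are dropped by default so that
    the "morphological species" unit of the barcode-error definitions is the
    binomial; set ``collapse_infraspecific=False`` to keep the full name.
    """
    toks = _tokens(taxon_name)
    if not collapse_infraspecific:
        return " ".join(toks)
    out: list[str] = []
    for t in toks:
        if t in INFRASPECIFIC_MARKERS:
            break
        out.append(t)
        if len(out) == 2:
            break
    return " ".join(out)


@dataclass
class SpecimenRecord:
    """One vouchered collection: sequence, taxonomy, year, PCR outcome.

    ``region_coords`` are 0-based half-open offsets ``(its1_end, s58_start,
    s58_end)`` into ``sequence``; 1-based inclusive coordinates appear only in
    the feature-table output.
    """

    specimen_id: str
    taxon_name: str = ""
    sequence: Optional[str] = None
    genus: str = ""
    family: str = ""
    order_name: str = ""
    collection_year: Optional[int] = None
    pcr_positive: Optional[bool] = None
    sequence_positive: Optional[bool] = None
    region_coords: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        if not self.genus and self.taxon_name:
            self.genus = parse_genus(self.taxon_name)
        if self.region_coords is not None:
            its1_end, s58_start, s58_end = self.region_coords
            n = len(self.sequence) if self.sequence else 0
            if not (0 < its1_end <= s58_start < s58_end <= n):
                raise ValueError(
                    f"{self.specimen_id}: invalid region coords {self.region_coords} "
                    f"for sequence length {n}"
                )

    @property
    def species(self) -> str:
        return binomial(self.taxon_name)

    @property
    def decade(self) -> Optional[int]:
        if self.collection_year is None:
            return None
        return (self.collection_year // 10) * 10


class TaxonomyIndex:
    """Genus → (family, order) lookup.

    Unresolved genera are a reportable condition, not an error: herbarium
    metadata routinely carries out-of-date nomenclature.
    """

    def __init__(self, mapping: Optional[dict[str, tuple[str, str]]] = None) -> None:
        self._map: dict[str, tuple[str, str]] = dict(mapping or {})

    def add(self, genus: str, family: str, order: str = "") -> None:
        self._map[genus] = (family, order)

    def __contains__(self, genus: str) -> bool:
        return genus in self._map

    def __len__(self) -> int:
        return len(self._map)

    def family_of(self, genus: str) -> Optional[str]:
        entry = self._map.get(genus)
        return entry[0] if entry else None

    def order_of(self, genus: str) -> Optional[str]:
        entry = self._map.get(genus)
        return entry[1] if entry else None

    def genera(self) -> list[str]:
        return sorted(self._map)

    def as_rows(self) -> list[tuple[str, str, str]]:
        return [(g, f, o) for g, (f, o) in sorted(self._map.items())]


@dataclass
class Dataset:
    """Ordered specimen records plus the taxonomy index they resolve against."""

    records: list[SpecimenRecord] = field(default_factory=list)
    taxonomy: TaxonomyIndex = field(default_factory=TaxonomyIndex)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.specimen_id in seen:
                raise ValueError(f"duplicate specimen_id {r.specimen_id!r}")
            seen.add(r.specimen_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    def id_map(self) -> dict[str, SpecimenRecord]:
        return {r.specimen_id: r for r in self.records}

    def sequenced(self) -> list[SpecimenRecord]:
        return [r for r in self.records if r.sequence]

    def unresolved_genera(self) -> list[str]:
        """Genera not present in the taxonomy index (reported, never dropped)."""
        return sorted({r.genus for r in self.records if r.genus and r.genus not in self.taxonomy})

    def validate(self) -> list[str]:
        """Non-fatal consistency report (genus/taxon-name disagreements etc.)."""
        issues = []
        for r in self.records:
            parsed = parse_genus(r.taxon_name)
            if r.genus and parsed and r.genus != parsed:
                issues.append(
                    f"{r.specimen_id}: genus column {r.genus!r} disagrees with "
                    f"taxon name {r.taxon_name!r}"
                )
        for g in self.unresolved_genera():
            issues.append(f"genus {g!r} not in taxonomy index")
        return issues

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            sp = r.species
            if sp:
                counts[sp] = counts.get(sp, 0) + 1
        return counts


def unique_taxa(records: Iterable[SpecimenRecord]) -> int:
    """Number of distinct binomials among *records*."""
    return len({r.species for r in records if r.species})
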