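"""Shared fixtures: tiny synthetic collections and hand-built matrices."""

from __future__ import annotations

import pytest

import barcodeaudit as ba
from barcodeaudit.distance import PairComparison, SparseDistanceMatrix
from barcodeaudit.records import Dataset, SpecimenRecord, TaxonomyIndex


def make_matrix(
    dists: dict[tuple[str, str], int],
    species: dict[str, str] | None = None,
    nonretained: list[tuple[str, str]] | None = None,
    threshold_bp: int = 70,
) -> SparseDistanceMatrix:
    """Build a SparseDistanceMatrix directly from pair distances (test helper)."""
    ids = sorted({i for pair in dists for i in pair}
                 | {i for pair in (nonretained or []) for i in pair})
    species = species or {i: f"Sp {i}" for i in ids}
    m = SparseDistanceMatrix(ids=ids, threshold_bp=threshold_bp)
    for (a, b), d in dists.items():
        a, b = sorted((a, b))
        m.entries[(a, b)] = PairComparison(
            id_a=a, id_b=b, bp_diff=d, retained=True,
            same_species=species[a] == species[b],
            same_genus=species[a].split()[0] == species[b].split()[0],
            same_family=False,
        )
    for a, b in nonretained or []:
        a, b = sorted((a, b))
        m.nonretained[(a, b)] = PairComparison(
            id_a=a, id_b=b, bp_diff=None, retained=False,
            same_species=species[a] == species[b],
            same_genus=species[a].split()[0] == species[b].split()[0],
            same_family=False,
        )
    return m


def make_dataset(specs: dict[str, tuple[str, str | None]], taxonomy: dict[str, tuple[str, str]] | None = None) -> Dataset:
    """Dataset from {specimen_id: (taxon_name, sequence)} (test helper)."""
    tax = TaxonomyIndex(taxonomy or {})
    records = [
        SpecimenRecord(specimen_id=sid, taxon_name=name, sequence=seq,
                       family=tax.family_of(name.split()[0]) or "",
                       order_name=tax.order_of(name.split()[0]) or "")
        for sid, (name, seq) in specs.items()
    ]
    return Dataset(records=records, taxonomy=tax)


@pytest.fixture(scope="session")
def small_dataset():
    """4 genera x 3 species x 2 accessions, defaults, no injections."""
    return ba.generate(ba.GeneratorConfig(
        n_genera=4, species_per_genus=3, accessions_per_species=2, seed=11))


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    dataset, _truth = small_dataset
    return ba.build_matrix(dataset)
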