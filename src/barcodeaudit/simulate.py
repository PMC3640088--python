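"""Synthetic herbarium-collection generator with known ground truth.

The generator emulates the statistical structure a barcode audit runs on: a
multi-genus, multi-species collection of ITS1+5.8S+ITS2 barcodes with a
conserved 5.8S, variable spacers, a controlled intra-/inter-specific
divergence contrast, injected identification errors, and age/taxon-dependent
PCR success.

The genealogy is star-shaped: a genus ancestor's spacers are drawn i.i.d.
uniform over {A,C,G,T}; each species ancestor substitutes per site at
``p_inter``; each accession substitutes from its species ancestor at
``p_intra``.  Substitutions go uniformly to the 3 alternative bases, so every
analytic expectation below follows from a simple per-site channel.  The
5.8S is one shared sequence (mutation rate 0 by default), giving the region
splitter a perfect anchor.

Error injections:

* false negative — one accession's sequence duplicated under a different
  congeneric species name (identical barcodes, different morphospecies);
* false positive — one accession of a species regenerated as an independent
  species-level lineage (divergent barcodes, one morphospecies);
* major misidentification — one accession relabeled with a species of a
  genus from a different family, sequence untouched.

All randomness flows from one seeded generator stream; a run is a pure
function of its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np

from .records import Dataset, SpecimenRecord, TaxonomyIndex

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def packaged_58s_consensus() -> str:
    """The packaged fungal 5.8S consensus used as generator core and split anchor."""
    text = resources.files("barcodeaudit.data").joinpath("fungal_58s_consensus.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


@dataclass(frozen=True)
class SuccessModel:
    """Logistic PCR-success model: logit(p) = intercept + per_decade_age * age_decades + genus offset.

    Age is measured in decades before ``reference_year``; negative
    ``per_decade_age`` makes older specimens amplify worse.  Defaults give a
    collection-wide success rate near 55%, falling with age.
    """

    intercept: float = 1.0
    per_decade_age: float = -0.5
    genus_offsets: tuple[tuple[str, float], ...] = ()
    reference_year: int = 2010
    seq_success_given_pcr: float = 0.58

    def probability(self, genus: str, year: int) -> float:
        offset = dict(self.genus_offsets).get(genus, 0.0)
        age_decades = (self.reference_year - year) / 10.0
        logit = self.intercept + self.per_decade_age * age_decades + offset
        return float(1.0 / (1.0 + np.exp(-logit)))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic collection."""

    n_genera: int = 8
    species_per_genus: int = 4
    accessions_per_species: int = 3
    len_its1: int = 250
    len_58s: int = 160
    len_its2: int = 250
    p_intra: float = 0.005
    p_inter: float = 0.05
    p_genus: float = 0.20
    p_58s: float = 0.0
    spacer_bias: float = 0.5
    n_false_neg_injected: int = 0
    n_false_pos_injected: int = 0
    n_major_misid_injected: int = 0
    year_range: tuple[int, int] = (1980, 2005)
    success_model: SuccessModel = field(default_factory=SuccessModel)
    genera_per_family: int = 2
    families_per_order: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_intra", "p_inter", "p_genus", "p_58s", "spacer_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("len_its1", "len_58s", "len_its2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class InjectedError:
    kind: str  # false_neg | false_pos | major_misid
    specimens: tuple[str, ...]
    species: tuple[str, ...]


@dataclass
class GroundTruth:
    """Everything a test oracle needs: true labels, injections, success probs."""

    true_species: dict[str, str] = field(default_factory=dict)
    injected: list[InjectedError] = field(default_factory=list)
    success_prob: dict[str, float] = field(default_factory=dict)
    region_coords: tuple[int, int, int] = (0, 0, 0)

    def injected_of(self, kind: str) -> list[InjectedError]:
        return [e for e in self.injected if e.kind == kind]


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at *rate*, uniform over the 3 alternative bases."""
    out = arr.copy()
    if rate <= 0.0:
        return out
    mask = rng.random(arr.size) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


def _region_rates(p: float, spacer_bias: float) -> tuple[float, float]:
    """Split a nominal spacer rate into ITS1/ITS2 rates by mutation routing.

    ``spacer_bias`` is the fraction of spacer mutations routed to ITS1; with
    equal spacer lengths the two-region average rate stays ``p``.
    """
    return min(1.0, 2.0 * spacer_bias * p), min(1.0, 2.0 * (1.0 - spacer_bias) * p)


def generate(config: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Generate one synthetic collection; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)

    s58_base = packaged_58s_consensus()
    reps = -(-config.len_58s // len(s58_base))
    s58_arr_base = np.frombuffer((s58_base * reps)[: config.len_58s].encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    s58_codes = lut[s58_arr_base]

    taxonomy = TaxonomyIndex()
    genus_names = [f"Genus{g + 1:02d}" for g in range(config.n_genera)]
    genus_family: dict[str, str] = {}
    for g, genus in enumerate(genus_names):
        fam_idx = g // config.genera_per_family
        ord_idx = fam_idx // config.families_per_order
        family = f"Family{fam_idx + 1:02d}"
        order = f"Order{ord_idx + 1:02d}"
        taxonomy.add(genus, family, order)
        genus_family[genus] = family

    r1_intra, r2_intra = _region_rates(config.p_intra, config.spacer_bias)
    r1_inter, r2_inter = _region_rates(config.p_inter, config.spacer_bias)

    coords = (config.len_its1, config.len_its1, config.len_its1 + config.len_58s)

    records: list[SpecimenRecord] = []
    truth = GroundTruth(region_coords=coords)
    # per-accession spacer arrays kept for injections
    spacers: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    genus_ancestors: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    idx = 0
    for genus in genus_names:
        anc1 = rng.integers(0, 4, size=config.len_its1, dtype=np.uint8)
        anc2 = rng.integers(0, 4, size=config.len_its2, dtype=np.uint8)
        genus_ancestors[genus] = (anc1, anc2)
        for s in range(config.species_per_genus):
            sp1 = _mutate(anc1, r1_inter, rng)
            sp2 = _mutate(anc2, r2_inter, rng)
            species_name = f"{genus} species{s + 1:02d}"
            for _a in range(config.accessions_per_species):
                idx += 1
                sid = f"S{idx:04d}"
                a1 = _mutate(sp1, r1_intra, rng)
                a2 = _mutate(sp2, r2_intra, rng)
                a58 = _mutate(s58_codes, config.p_58s, rng)
                year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
                p_succ = config.success_model.probability(genus, year)
                pcr = bool(rng.random() < p_succ)
                seq_pos = bool(pcr and rng.random() < config.success_model.seq_success_given_pcr)
                spacers[sid] = (a1, a2)
                records.append(
                    SpecimenRecord(
                        specimen_id=sid,
                        taxon_name=species_name,
                        sequence=_decode(a1) + _decode(a58) + _decode(a2),
                        genus=genus,
                        family=taxonomy.family_of(genus) or "",
                        order_name=taxonomy.order_of(genus) or "",
                        collection_year=year,
                        pcr_positive=pcr,
                        sequence_positive=seq_pos,
                        region_coords=coords,
                    )
                )
                truth.true_species[sid] = species_name
                truth.success_prob[sid] = p_succ

    by_species: dict[str, list[SpecimenRecord]] = {}
    for r in records:
        by_species.setdefault(r.taxon_name, []).append(r)
    used: set[str] = set()

    _inject_false_negatives(config, rng, records, by_species, used, truth)
    _inject_false_positives(config, rng, genus_ancestors, spacers, s58_codes,
                            r1_inter, r2_inter, r1_intra, r2_intra,
                            by_species, used, truth)
    _inject_major_misids(config, rng, records, genus_names, genus_family, taxonomy, used, truth)

    return Dataset(records=records, taxonomy=taxonomy), truth


def _inject_false_negatives(config, rng, records, by_species, used, truth) -> None:
    if not config.n_false_neg_injected:
        return
    candidates = []
    genera: dict[str, list[str]] = {}
    for sp in by_species:
        genera.setdefault(sp.split()[0], []).append(sp)
    for genus, splist in sorted(genera.items()):
        splist = sorted(splist)
        for i in range(0, len(splist) - 1, 2):  # disjoint species pairs
            candidates.append((splist[i], splist[i + 1]))
    if len(candidates) < config.n_false_neg_injected:
        raise ValueError(
            f"cannot inject {config.n_false_neg_injected} false negatives: "
            f"only {len(candidates)} disjoint congeneric species pairs available"
        )
    picks = rng.choice(len(candidates), size=config.n_false_neg_injected, replace=False)
    for k in sorted(picks):
        sp_a, sp_b = candidates[k]
        donor = by_species[sp_a][0]
        target = by_species[sp_b][0]
        target.sequence = donor.sequence
        used.update({donor.specimen_id, target.specimen_id})
        truth.injected.append(
            InjectedError("false_neg", (donor.specimen_id, target.specimen_id), (sp_a, sp_b))
        )


def _inject_false_positives(config, rng, genus_ancestors, spacers, s58_codes,
                            r1_inter, r2_inter, r1_intra, r2_intra,
                            by_species, used, truth) -> None:
    if not config.n_false_pos_injected:
        return
    candidates = [
        sp for sp, accs in sorted(by_species.items())
        if len(accs) >= 2 and not any(a.specimen_id in used for a in accs)
    ]
    if len(candidates) < config.n_false_pos_injected:
        raise ValueError(
            f"cannot inject {config.n_false_pos_injected} false positives: "
            f"only {len(candidates)} eligible multi-accession species"
        )
    picks = rng.choice(len(candidates), size=config.n_false_pos_injected, replace=False)
    for k in sorted(picks):
        sp = candidates[k]
        target = by_species[sp][1]
        genus = sp.split()[0]
        anc1, anc2 = genus_ancestors[genus]
        lin1 = _mutate(_mutate(anc1, r1_inter, rng), r1_intra, rng)
        lin2 = _mutate(_mutate(anc2, r2_inter, rng), r2_intra, rng)
        a58 = _mutate(s58_codes, config.p_58s, rng)
        target.sequence = _decode(lin1) + _decode(a58) + _decode(lin2)
        spacers[target.specimen_id] = (lin1, lin2)
        used.update(a.specimen_id for a in by_species[sp])
        truth.injected.append(
            InjectedError("false_pos", (by_species[sp][0].specimen_id, target.specimen_id), (sp,))
        )


def _inject_major_misids(config, rng, records, genus_names, genus_family, taxonomy, used, truth) -> None:
    if not config.n_major_misid_injected:
        return
    candidates = [r for r in records if r.specimen_id not in used]
    eligible = []
    for r in candidates:
        foreign = [g for g in genus_names if genus_family[g] != genus_family[r.genus]]
        if foreign:
            eligible.append((r, foreign))
    if len(eligible) < config.n_major_misid_injected:
        raise ValueError(
            f"cannot inject {config.n_major_misid_injected} major misidentifications: "
            f"only {len(eligible)} eligible accessions"
        )
    picks = rng.choice(len(eligible), size=config.n_major_misid_injected, replace=False)
    for k in sorted(picks):
        rec, foreign = eligible[k]
        new_genus = foreign[int(rng.integers(len(foreign)))]
        old_species = rec.taxon_name
        rec.taxon_name = f"{new_genus} species01"
        rec.genus = new_genus
        rec.family = taxonomy.family_of(new_genus) or ""
        rec.order_name = taxonomy.order_of(new_genus) or ""
        used.add(rec.specimen_id)
        truth.injected.append(
            InjectedError("major_misid", (rec.specimen_id,), (old_species, rec.taxon_name))
        )


# --- analytic companion --------------------------------------------------------

def _p_compose(p: float, r: float) -> float:
    """Error rate of two uniform-substitution rounds (rate p then r) composed."""
    return 1.0 - ((1.0 - p) * (1.0 - r) + p * r / 3.0)


def _p_differ(pa: float, pb: float) -> float:
    """P(two sites differ) when each lineage substitutes from a shared ancestor.

    A differs from the ancestor with probability pa (uniform over the 3
    alternatives), B with pb; they agree either by both staying (first term)
    or by landing on the same alternative (pa*pb/3).
    """
    return 1.0 - (1.0 - pa) * (1.0 - pb) - pa * pb / 3.0


def expected_pair_divergence(config: GeneratorConfig) -> dict[str, float]:
    """Exact expected bp differences per pair class under the generator model.

    Returns expectations for ``intra`` (same species), ``inter`` (congeneric,
    different species) and ``between_genus`` (independent uniform ancestors,
    3/4 per spacer site) pairs.  The 5.8S contributes at rate ``p_58s``.
    """
    r1_a, r2_a = _region_rates(config.p_intra, config.spacer_bias)
    r1_e, r2_e = _region_rates(config.p_inter, config.spacer_bias)
    L1, L2, L58 = config.len_its1, config.len_its2, config.len_58s

    e58 = L58 * _p_differ(config.p_58s, config.p_58s)
    intra = L1 * _p_differ(r1_a, r1_a) + L2 * _p_differ(r2_a, r2_a) + e58

    eff1 = _p_compose(r1_e, r1_a)
    eff2 = _p_compose(r2_e, r2_a)
    inter = L1 * _p_differ(eff1, eff1) + L2 * _p_differ(eff2, eff2) + e58

    between = 0.75 * (L1 + L2) + e58
    return {"intra": intra, "inter": inter, "between_genus": between}


def write_dataset_files(dataset: Dataset, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write FASTA + metadata + taxonomy files consumable by the ingest stage."""
    from . import seqio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "sequences.fasta",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
    }
    seqio.write_fasta({r.specimen_id: r.sequence for r in dataset.records if r.sequence}, paths["fasta"])
    lines = ["specimen_id\ttaxon_name\tgenus\tfamily\torder\tcollection_year\tpcr_positive\tsequence_positive"]
    for r in dataset.records:
        lines.append(
            "\t".join(
                [
                    r.specimen_id, r.taxon_name, r.genus, r.family, r.order_name,
                    "" if r.collection_year is None else str(r.collection_year),
                    "" if r.pcr_positive is None else str(int(r.pcr_positive)),
                    "" if r.sequence_positive is None else str(int(r.sequence_positive)),
                ]
            )
        )
    paths["metadata"].write_text("\n".join(lines) + "\n")
    tax_lines = ["genus\tfamily\torder"] + ["\t".join(row) for row in dataset.taxonomy.as_rows()]
    paths["taxonomy"].write_text("\n".join(tax_lines) + "\n")
    return paths
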