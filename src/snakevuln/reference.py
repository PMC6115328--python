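"""Published reference inputs for the global snakebite vulnerability analysis.

Two small bundled datasets reproduce the published study's tabular
inputs so the reporting code paths can be exercised (and their headline
arithmetic recomputed) without the proprietary global rasters:

* the country-level vulnerable-population counts per HAQ Index decile
  (people within the range of >= 1 medically important venomous snake
  with no listed therapy, > 3 h from an urban centre), as printed in the
  published global assessment;
* the composition of the WHO species registry used there: 287 assessed
  species of which 9 lacked both an expert-opinion range map and
  occurrence records (group A, excluded), 99 had a range map but < 5
  records (group B), 179 had a range map and >= 5 records (group C), and
  159 of the 278 included species have some listed antivenom (24 of the
  119 therapy-less species are WHO category 1).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .registry import SpeciesRecord

__all__ = [
    "load_vulnerable_by_decile",
    "published_registry",
    "published_antivenom_table",
    "PUBLISHED_COUNTS",
]

PUBLISHED_COUNTS = {
    "n_assessed": 287,
    "n_group_a": 9,
    "n_group_b": 99,
    "n_group_c": 179,
    "n_included": 278,
    "n_antivenom_available": 159,
    "n_no_antivenom": 119,
    "n_no_antivenom_cat1": 24,
    "n_no_antivenom_cat2": 95,
}


def load_vulnerable_by_decile() -> pd.DataFrame:
    """Long-format published table: country, decile, population_vulnerable."""
    with resources.files("snakevuln").joinpath("data/vulnerable_by_decile.csv").open() as fh:
        df = pd.read_csv(fh)
    df["population_vulnerable"] = df["population_vulnerable"].astype(float)
    return df


def published_registry() -> list[SpeciesRecord]:
    """A registry with the published availability-group composition.

    Species identities are synthetic placeholders; the has_eor /
    record-count / category / therapy structure matches the published
    tallies so that group assignment, summary, and antivenom-join logic
    reproduce the study's registry arithmetic when run on it.
    """
    c = PUBLISHED_COUNTS
    species: list[SpeciesRecord] = []
    k = 0

    def add(n: int, *, has_eor: bool, n_records: int, category: int) -> None:
        nonlocal k
        for _ in range(n):
            k += 1
            species.append(
                SpeciesRecord(
                    species_id=f"sp{k:03d}",
                    name=f"Serpens synthetica {k}",
                    who_category=category,
                    has_eor=has_eor,
                    n_records=n_records,
                )
            )

    add(c["n_group_a"], has_eor=False, n_records=0, category=2)
    # therapy-less included species first: 24 category 1, then 95 category 2
    add(c["n_no_antivenom_cat1"], has_eor=True, n_records=3, category=1)
    add(c["n_no_antivenom_cat2"], has_eor=True, n_records=7, category=2)
    # remaining included species (therapy available): fill group B to 99,
    # group C to 179
    n_b_left = c["n_group_b"] - c["n_no_antivenom_cat1"]
    n_c_left = c["n_group_c"] - c["n_no_antivenom_cat2"]
    add(n_b_left, has_eor=True, n_records=2, category=1)
    add(n_c_left, has_eor=True, n_records=12, category=2)
    return species


def published_antivenom_table(species: list[SpeciesRecord]) -> dict[str, bool]:
    """Availability flags matching the published 159-available split.

    The first 119 included species of :func:`published_registry` are the
    therapy-less ones; everything else included is marked available.
    """
    table: dict[str, bool] = {}
    n_no = PUBLISHED_COUNTS["n_no_antivenom"]
    seen_included = 0
    for s in species:
        if not s.has_eor:
            continue
        seen_included += 1
        table[s.species_id] = seen_included > n_no
    return table
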