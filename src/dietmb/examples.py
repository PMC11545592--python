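"""Bundled worked example: a dark-sleeper faecal diet dataset.

The example mirrors a 24-sample faecal metabarcoding study of the dark
sleeper (*Odontobutis obscurus*), a carnivorous freshwater fish: a
best-hit table of 15 prey taxa (7 fish, 8 benthic invertebrates, two
congeneric pairs that merge at genus rank), a genus-level field survey
of fish and benthos availability, and a read-count table. The hit
identities/scores follow the shape of real BLAST output; the read
counts and survey counts are synthetic (drawn from a seeded generator)
since the example exists to exercise the pipeline end to end, not to
reproduce any particular survey.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import (
    GROUP_FISH,
    GROUP_INVERT,
    FieldSurveyTable,
    ReadCountTable,
    TaxonomyHit,
)

# (taxon, max_score, identity, query coverage, accession) — 15 prey taxa
# spanning 13 genera; "sp." entries are genus-level calls.
_EXAMPLE_TAXA: tuple[tuple[str, float, float, float, str], ...] = (
    ("Micropterus salmoides", 579, 100.0, 100, "MT455106.1"),
    ("Misgurnus anguillicaudatus", 579, 100.0, 100, "MF122502.1"),
    ("Carassius cuvieri", 579, 100.0, 100, "MT571744.1"),
    ("Zacco sp. 1", 556, 98.7, 100, "MT457508.1"),
    ("Zacco sp. 2", 579, 100.0, 100, "MT457518.1"),
    ("Rhinogobius brunneus", 579, 100.0, 100, "OL674307.1"),
    ("Hemibarbus labeo", 573, 99.7, 100, "OL674364.1"),
    ("Chironomus flaviplumus", 534, 97.4, 100, "MN521255.1"),
    ("Cricotopus triannulatus", 579, 100.0, 100, "LC050962.1"),
    ("Polypedilum japonicum", 573, 99.7, 100, "LC329191.1"),
    ("Polypedilum yongsanensis", 579, 100.0, 100, "NC_072650.1"),
    ("Ephemera orientalis", 562, 99.0, 100, "OL664518.1"),
    ("Platycnemis phyllopoda", 573, 99.7, 100, "KF257109.1"),
    ("Radix sp.", 564, 99.0, 100, "LC658589.1"),
    ("Limnodrilus sp.", 579, 100.0, 100, "KY369698.1"),
)

#: field availability: fish surveyed at the faecal sampling reach, benthos
#: at a nearby reference reach. Counts are synthetic.
_EXAMPLE_SURVEY: tuple[tuple[str, str, str, int], ...] = (
    (GROUP_FISH, "Zacco", "Z. temminckii", 180),
    (GROUP_FISH, "Zacco", "Z. koreanus", 60),
    (GROUP_FISH, "Rhinogobius", "R. brunneus", 90),
    (GROUP_FISH, "Misgurnus", "M. anguillicaudatus", 25),
    (GROUP_FISH, "Carassius", "C. cuvieri", 12),
    (GROUP_FISH, "Squalidus", "S. gracilis", 40),
    (GROUP_FISH, "Opsariichthys", "O. uncirostris", 30),
    (GROUP_FISH, "Pseudogobio", "P. esocinus", 22),
    (GROUP_FISH, "Cobitis", "C. hankugensis", 15),
    (GROUP_FISH, "Silurus", "S. asotus", 6),
    (GROUP_FISH, "Odontobutis", "O. obscurus", 55),
    (GROUP_INVERT, "Chironomus", "", 140),
    (GROUP_INVERT, "Polypedilum", "", 120),
    (GROUP_INVERT, "Ephemera", "E. orientalis", 80),
    (GROUP_INVERT, "Radix", "R. auricularia", 35),
    (GROUP_INVERT, "Baetis", "", 160),
    (GROUP_INVERT, "Ecdyonurus", "", 70),
    (GROUP_INVERT, "Epeorus", "", 45),
    (GROUP_INVERT, "Caenis", "", 30),
    (GROUP_INVERT, "Ephemerella", "", 55),
    (GROUP_INVERT, "Hydropsyche", "", 110),
    (GROUP_INVERT, "Cheumatopsyche", "", 85),
    (GROUP_INVERT, "Stenopsyche", "", 20),
    (GROUP_INVERT, "Glossosoma", "", 15),
    (GROUP_INVERT, "Rhyacophila", "", 25),
    (GROUP_INVERT, "Nemoura", "", 18),
    (GROUP_INVERT, "Gammarus", "", 95),
    (GROUP_INVERT, "Asellus", "", 40),
    (GROUP_INVERT, "Physa", "", 28),
    (GROUP_INVERT, "Semisulcospira", "", 60),
    (GROUP_INVERT, "Sphaerium", "", 14),
    (GROUP_INVERT, "Tubifex", "", 33),
)


def example_hits() -> list[TaxonomyHit]:
    """Best-hit table for the 15 example prey taxa (one OTU per taxon)."""
    return [
        TaxonomyHit(
            otu_id=f"OTU{n + 1:03d}",
            taxon=taxon,
            percent_identity=identity,
            query_coverage_pct=coverage,
            max_score=score,
            accession=accession,
        )
        for n, (taxon, score, identity, coverage, accession) in enumerate(_EXAMPLE_TAXA)
    ]


def example_survey() -> FieldSurveyTable:
    """Field availability table (10 fish genera, 21 benthos records)."""
    return FieldSurveyTable(
        pd.DataFrame(_EXAMPLE_SURVEY, columns=["group", "genus", "species", "count"])
    )


def example_count_table(n_samples: int = 24, seed: int = 7) -> ReadCountTable:
    """Synthetic 24 x 15 read-count table over the example OTUs.

    Counts are drawn once from a seeded generator with a dominant first
    Zacco OTU; every OTU clears the default 0.01% read threshold.
    """
    rng = np.random.default_rng(seed)
    n_otus = len(_EXAMPLE_TAXA)
    base = rng.integers(50, 4_000, size=(n_samples, n_otus))
    base[:, 3] += rng.integers(5_000, 40_000, size=n_samples)  # Zacco sp. 1 dominates
    samples = [f"F{k + 1:02d}" for k in range(n_samples)]
    otus = [f"OTU{n + 1:03d}" for n in range(n_otus)]
    return ReadCountTable(pd.DataFrame(base, index=samples, columns=otus))
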