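"""Quality-filter cascade and taxonomy harmonisation.

The cascade turns a raw sample x OTU count table plus per-OTU best hits
into a genus-level prey table:

1. **Read threshold** — OTUs whose dataset-wide read sum falls below a
   relative copy-number threshold (default 0.01% of the dataset total)
   are removed. This is the guard against low-level background noise
   such as secondary predation, cross-contamination and sequencing
   error. The cutoff is computed once from the *input* table's total.
2. **Taxonomic screen** — surviving OTUs are dropped when their best hit
   is the host species, ``"no match"``, a configured non-prey taxon
   (fungi, Chromista, livestock, ...), or below the identity threshold
   (default >= 97%).
3. **Harmonisation with the field survey** — a kept species that was
   never recorded at the study site is demoted to genus rank
   (``"Genus sp."``); species confirmed in the survey keep their rank.
4. **Collapse** — reads of OTUs mapping to the same final taxon are
   summed per sample at the requested rank (genus by default); samples
   left without any prey reads are dropped with a warning.

Every input OTU appears exactly once in the audit trail with exactly one
kept/dropped reason, and total prey-table reads equal the total reads of
kept OTUs — both properties are enforced by the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .io import (
    NO_MATCH,
    GROUP_FISH,
    GROUP_INVERT,
    FieldSurveyTable,
    PreyTable,
    ReadCountTable,
    TaxonomyHit,
    ValidationError,
)

logger = logging.getLogger(__name__)

# kept/dropped reasons, exactly one per OTU
BELOW_READ_THRESHOLD = "below_read_threshold"
BELOW_IDENTITY = "below_identity"
HOST = "host"
NO_MATCH_REASON = "no_match"
NONPREY = "nonprey"
KEPT_SPECIES = "kept_species"
KEPT_DEMOTED = "kept_demoted_to_genus"

DROP_REASONS = (BELOW_READ_THRESHOLD, BELOW_IDENTITY, HOST, NO_MATCH_REASON, NONPREY)
KEEP_REASONS = (KEPT_SPECIES, KEPT_DEMOTED)

#: genus -> prey group for the taxa expected in a Korean stream diet study
DEFAULT_GENUS_GROUPS: dict[str, str] = {
    # fish
    "Zacco": GROUP_FISH,
    "Micropterus": GROUP_FISH,
    "Misgurnus": GROUP_FISH,
    "Carassius": GROUP_FISH,
    "Rhinogobius": GROUP_FISH,
    "Hemibarbus": GROUP_FISH,
    "Squalidus": GROUP_FISH,
    "Opsariichthys": GROUP_FISH,
    "Pseudogobio": GROUP_FISH,
    "Cobitis": GROUP_FISH,
    "Silurus": GROUP_FISH,
    # benthic invertebrates
    "Chironomus": GROUP_INVERT,
    "Cricotopus": GROUP_INVERT,
    "Polypedilum": GROUP_INVERT,
    "Ephemera": GROUP_INVERT,
    "Platycnemis": GROUP_INVERT,
    "Radix": GROUP_INVERT,
    "Limnodrilus": GROUP_INVERT,
    "Baetis": GROUP_INVERT,
    "Hydropsyche": GROUP_INVERT,
    "Physa": GROUP_INVERT,
    "Gammarus": GROUP_INVERT,
}


@dataclass
class FilterConfig:
    """Knobs of the filter cascade.

    ``min_relative_reads`` is a fraction of the dataset (or per-sample)
    read total: 0.0001 keeps OTUs at >= 0.01% of reads. ``min_identity``
    is the BLAST percent-identity floor for accepting a taxon call.
    ``nonprey_exclusions`` are matched case-insensitively against the
    full taxon name and against its genus token, so a clade label like
    ``"Fungi"`` catches ``"Fungi sp."``.
    """

    min_relative_reads: float = 1e-4
    min_identity: float = 97.0
    host_taxon: str = "Odontobutis obscurus"
    nonprey_exclusions: tuple[str, ...] = ("Fungi", "Chromista", "Bos taurus")
    collapse_rank: str = "genus"  # or "species"
    per_sample_threshold: bool = False
    min_query_coverage: float | None = None
    group_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GENUS_GROUPS))

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_relative_reads < 1.0:
            raise ValidationError("min_relative_reads must be in [0, 1)")
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValidationError("min_identity must be in [0, 100]")
        if self.collapse_rank not in ("species", "genus"):
            raise ValidationError("collapse_rank must be 'species' or 'genus'")


@dataclass
class TaxonAssignment:
    """Kept/dropped decision for one OTU, with exactly one reason."""

    otu_id: str
    final_taxon: str | None
    prey_group: str | None
    status: str  # "kept" | "dropped"
    reason: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("kept", "dropped"):
            raise ValidationError(f"bad status {self.status!r}")
        if (self.status == "kept") != (self.final_taxon is not None):
            raise ValidationError(
                f"OTU {self.otu_id!r}: status {self.status!r} inconsistent with "
                f"final_taxon {self.final_taxon!r}"
            )
        expected = KEEP_REASONS if self.status == "kept" else DROP_REASONS
        if self.reason not in expected:
            raise ValidationError(
                f"OTU {self.otu_id!r}: reason {self.reason!r} invalid for status "
                f"{self.status!r}"
            )


def genus_of(taxon: str) -> str:
    parts = taxon.split()
    return parts[0] if parts else ""


def is_genus_placeholder(taxon: str) -> bool:
    """True for genus-level names such as 'Zacco sp.' or 'Zacco sp. 2'."""
    parts = taxon.split()
    return len(parts) >= 2 and parts[1].lower().rstrip(".") == "sp"


def apply_read_threshold(
    table: ReadCountTable,
    min_relative_reads: float,
    per_sample: bool = False,
) -> tuple[ReadCountTable, list[dict]]:
    """Remove low-abundance OTUs; keep when share >= the threshold.

    Dataset-wide mode (default): an OTU survives when its read sum over
    all samples is at least ``min_relative_reads`` times the table's
    grand total. Per-sample mode zeroes cells below the per-sample
    cutoff first, then removes OTUs left with no reads anywhere.
    Returns the filtered table and an audit record per removed OTU.
    """
    if not 0.0 <= min_relative_reads < 1.0:
        raise ValidationError("min_relative_reads must be in [0, 1)")
    total = table.total_reads
    audit: list[dict] = []
    if per_sample:
        counts = table.counts.copy()
        sample_totals = counts.sum(axis=1)
        cutoff = (sample_totals * min_relative_reads).to_numpy()[:, None]
        counts = counts.where(counts.to_numpy() >= cutoff, 0)
        keep = counts.sum(axis=0) > 0
    else:
        otu_sums = table.counts.sum(axis=0)
        cutoff = min_relative_reads * total
        keep = otu_sums >= cutoff
        counts = table.counts
    for otu in table.otu_ids:
        if not keep[otu]:
            reads = int(table.counts[otu].sum())
            audit.append(
                {
                    "otu_id": otu,
                    "reads": reads,
                    "relative_share": reads / total if total else 0.0,
                    "reason": BELOW_READ_THRESHOLD,
                }
            )
    kept_ids = [o for o in table.otu_ids if keep[o]]
    if not kept_ids:
        raise ValidationError("read threshold removed every OTU")
    return ReadCountTable(counts.loc[:, kept_ids].copy()), audit


def assign_taxa(
    hits: Sequence[TaxonomyHit], config: FilterConfig
) -> list[TaxonAssignment]:
    """Screen best hits, keeping OTUs provisionally at species rank.

    Exclusion order: "no match", host, non-prey, identity (and optional
    query-coverage) thresholds. A kept OTU must have a prey-group
    mapping for its genus in ``config.group_map``.
    """
    seen: set[str] = set()
    exclusions = {e.strip().lower() for e in config.nonprey_exclusions}
    out: list[TaxonAssignment] = []
    for hit in hits:
        if hit.otu_id in seen:
            raise ValidationError(f"duplicate hit for OTU {hit.otu_id!r}")
        seen.add(hit.otu_id)
        taxon = hit.taxon.strip()
        if hit.is_no_match:
            out.append(TaxonAssignment(hit.otu_id, None, None, "dropped", NO_MATCH_REASON))
            continue
        if taxon.lower() == config.host_taxon.strip().lower():
            out.append(TaxonAssignment(hit.otu_id, None, None, "dropped", HOST))
            continue
        if taxon.lower() in exclusions or hit.genus.lower() in exclusions:
            out.append(TaxonAssignment(hit.otu_id, None, None, "dropped", NONPREY))
            continue
        if hit.percent_identity < config.min_identity:
            out.append(TaxonAssignment(hit.otu_id, None, None, "dropped", BELOW_IDENTITY))
            continue
        if (
            config.min_query_coverage is not None
            and hit.query_coverage_pct < config.min_query_coverage
        ):
            out.append(TaxonAssignment(hit.otu_id, None, None, "dropped", BELOW_IDENTITY,
                                       note="below query-coverage minimum"))
            continue
        genus = hit.genus
        if genus not in config.group_map:
            raise ValidationError(
                f"OTU {hit.otu_id!r}: kept taxon {taxon!r} has no prey-group "
                f"mapping for genus {genus!r}"
            )
        out.append(
            TaxonAssignment(
                hit.otu_id,
                taxon,
                config.group_map[genus],
                "kept",
                KEPT_SPECIES,
            )
        )
    return out


def harmonise_with_field_survey(
    assignments: Sequence[TaxonAssignment], survey: FieldSurveyTable
) -> list[TaxonAssignment]:
    """Demote kept species not recorded in the field survey to genus rank.

    Species present in the survey keep their rank; species absent while
    the genus was recorded become ``"Genus sp."``; species whose genus is
    also absent are likewise kept at genus rank but flagged in the note
    (faecal-only taxa are retained, not discarded).
    """
    out: list[TaxonAssignment] = []
    for a in assignments:
        if a.status != "kept" or a.final_taxon is None:
            out.append(a)
            continue
        taxon = a.final_taxon
        genus = genus_of(taxon)
        if is_genus_placeholder(taxon):
            out.append(a)  # already genus-level
            continue
        if survey.has_species(genus, taxon):
            out.append(a)
            continue
        note = "" if genus in survey.genera() else "genus absent from field survey"
        out.append(replace(a, final_taxon=f"{genus} sp.", reason=KEPT_DEMOTED, note=note))
    return out


def collapse_to_prey_table(
    table: ReadCountTable,
    assignments: Sequence[TaxonAssignment],
    rank: str = "genus",
) -> PreyTable:
    """Sum reads of kept OTUs into prey items at the requested rank.

    At genus rank every kept OTU becomes ``"Genus sp."``; at species rank
    the final taxon labels are used as-is. Samples left with zero prey
    reads are dropped with a warning.
    """
    if rank not in ("species", "genus"):
        raise ValidationError("rank must be 'species' or 'genus'")
    by_otu = {a.otu_id: a for a in assignments}
    item_cols: dict[str, list[str]] = {}
    item_groups: dict[str, str] = {}
    for otu in table.otu_ids:
        a = by_otu.get(otu)
        if a is None or a.status != "kept":
            continue
        name = f"{genus_of(a.final_taxon)} sp." if rank == "genus" else a.final_taxon
        item_cols.setdefault(name, []).append(otu)
        prev = item_groups.setdefault(name, a.prey_group)
        if prev != a.prey_group:
            raise ValidationError(
                f"prey item {name!r} maps to conflicting groups {prev!r} / "
                f"{a.prey_group!r}"
            )
    if not item_cols:
        raise ValidationError("no kept OTUs; cannot build a prey table")
    data = {name: table.counts[cols].sum(axis=1) for name, cols in item_cols.items()}
    counts = pd.DataFrame(data, index=table.counts.index)
    empty = counts.index[counts.sum(axis=1) == 0].tolist()
    if empty:
        logger.warning("dropping %d sample(s) with zero prey reads: %s", len(empty), empty)
        counts = counts.drop(index=empty)
    if counts.shape[0] == 0:
        raise ValidationError("every sample has zero prey reads")
    return PreyTable(counts, item_groups, dropped_samples=[str(s) for s in empty])


@dataclass
class FilterResult:
    """Bundle returned by the full cascade."""

    prey: PreyTable
    assignments: list[TaxonAssignment]
    audit: pd.DataFrame
    thresholded: ReadCountTable


def run_filter_pipeline(
    table: ReadCountTable,
    hits: Sequence[TaxonomyHit],
    survey: FieldSurveyTable | None = None,
    config: FilterConfig | None = None,
) -> FilterResult:
    """Threshold -> taxon screen -> survey harmonisation -> collapse.

    OTUs present in the count table but absent from the hit list are
    synthesised as ``"no match"``. Without a survey the harmonisation
    step is skipped (all kept species stay at species rank).
    """
    config = config or FilterConfig()
    hit_map = {h.otu_id: h for h in hits}
    extra = [h for h in hits if h.otu_id not in set(table.otu_ids)]
    if extra:
        logger.warning(
            "%d taxonomy hit(s) refer to OTUs absent from the count table", len(extra)
        )
    full_hits = [
        hit_map.get(
            otu,
            TaxonomyHit(otu, NO_MATCH, 0.0, 0.0, 0.0, ""),
        )
        for otu in table.otu_ids
    ]
    thresholded, threshold_audit = apply_read_threshold(
        table, config.min_relative_reads, per_sample=config.per_sample_threshold
    )
    surviving = set(thresholded.otu_ids)
    assignments = assign_taxa([h for h in full_hits if h.otu_id in surviving], config)
    if survey is not None:
        assignments = harmonise_with_field_survey(assignments, survey)
    prey = collapse_to_prey_table(thresholded, assignments, rank=config.collapse_rank)

    # audit: one row per input OTU, exactly one reason each
    total = table.total_reads
    by_otu = {a.otu_id: a for a in assignments}
    removed = {rec["otu_id"]: rec for rec in threshold_audit}
    rows = []
    for otu in table.otu_ids:
        hit = hit_map.get(otu)
        reads = int(table.counts[otu].sum())
        if otu in removed:
            status, reason, final, note = "dropped", BELOW_READ_THRESHOLD, "", ""
        else:
            a = by_otu[otu]
            status, reason, note = a.status, a.reason, a.note
            if a.status == "kept":
                final = (
                    f"{genus_of(a.final_taxon)} sp."
                    if config.collapse_rank == "genus"
                    else a.final_taxon
                )
            else:
                final = ""
        rows.append(
            {
                "otu_id": otu,
                "reads": reads,
                "relative_share": reads / total if total else 0.0,
                "taxon": hit.taxon if hit is not None else NO_MATCH,
                "identity": hit.percent_identity if hit is not None else float("nan"),
                "status": status,
                "reason": reason,
                "final_item": final,
                "note": note,
            }
        )
    audit = pd.DataFrame(rows)
    return FilterResult(prey=prey, assignments=assignments, audit=audit, thresholded=thresholded)
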