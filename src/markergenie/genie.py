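"""Marker-gene inventories: variant counting, per-sample tables, export.

This is the reporting layer: accepted ORFs are grouped by taxonomic
lineage (phylum level; class level for Proteobacteria) and gene symbol,
de-replicated into sequence variants, and summarised per sample as the
lineage x gene x sample table behind the dot-plot style figure — dot
size being the number of distinct gene variants ("transcript copies"),
not read-depth abundance.  Samples carry site, depth (mbsf) and sulfate
status metadata so the export stratifies by geochemical context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .calibrate import competitive_assign
from .errors import ValidationError
from .genefinder import Orf
from .registry import GeneFamilyRegistry

UNCLASSIFIED = "unclassified"

FIG2_COLUMNS = [
    "site", "depth_mbsf", "sulfate_status", "lineage",
    "gene_symbol", "category", "transcript_copies",
]


@dataclass
class SampleMeta:
    """Where a sample comes from: site, burial depth, sulfate regime."""

    sample_id: str
    site: str
    depth_mbsf: float
    sulfate_status: str  # 'present' or 'depleted'

    def validate(self) -> None:
        if self.depth_mbsf < 0:
            raise ValidationError(f"{self.sample_id}: negative depth")
        if self.sulfate_status not in ("present", "depleted"):
            raise ValidationError(
                f"{self.sample_id}: sulfate_status must be 'present' or 'depleted'"
            )


@dataclass
class InventoryRow:
    lineage: str
    gene_symbol: str
    category: str
    variant_count: int
    orf_ids: list[str] = field(default_factory=list)


@dataclass
class SampleInventory:
    """Per-sample (lineage, gene) variant counts with supporting ORFs."""

    sample: SampleMeta
    rows: list[InventoryRow] = field(default_factory=list)

    def validate(self) -> None:
        seen = set()
        for r in self.rows:
            if r.variant_count < 1:
                raise ValidationError("inventory rows must have variant_count >= 1")
            if r.variant_count > len(r.orf_ids):
                raise ValidationError("variant_count exceeds number of supporting ORFs")
            key = (r.lineage, r.gene_symbol)
            if key in seen:
                raise ValidationError(f"duplicate inventory row {key}")
            seen.add(key)

    def total_variants(self) -> int:
        return sum(r.variant_count for r in self.rows)


# ---------------------------------------------------------------------------
# Variant counting
# ---------------------------------------------------------------------------

def _overlap_identity(a: str, b: str) -> float:
    """Identity of the best ungapped overlap, over the shorter sequence."""
    if len(a) < len(b):
        a, b = b, a
    la, lb = len(a), len(b)
    best = 0
    for off in range(-lb + 1, la):
        lo = max(0, off)
        hi = min(la, off + lb)
        matches = sum(1 for i in range(lo, hi) if a[i] == b[i - off])
        if matches > best:
            best = matches
    return best / lb


def count_variants(
    orfs: Sequence[Orf],
    identity_threshold: float = 1.0,
) -> tuple[int, list[list[str]]]:
    """Greedy de-replication of same-gene ORFs into sequence variants.

    ORFs (sorted longest first, then lexicographically) join the first
    existing cluster whose representative they match at
    ``identity_threshold`` identity over the shorter sequence (best
    ungapped overlap).  At threshold 1.0 this reduces to exact
    substring/duplicate de-replication.  Returns the variant count and
    the clusters as lists of orf_ids.
    """
    if not orfs:
        raise ValidationError("count_variants requires at least one ORF")
    if not (0 < identity_threshold <= 1):
        raise ValidationError("identity_threshold must be in (0, 1]")
    ordered = sorted(orfs, key=lambda o: (-len(o.aa_seq), o.aa_seq, o.orf_id))
    reps: list[str] = []
    clusters: list[list[str]] = []
    for o in ordered:
        placed = False
        for ci, rep in enumerate(reps):
            if identity_threshold >= 1.0:
                ok = o.aa_seq in rep  # rep is always >= as long
            else:
                ok = _overlap_identity(rep, o.aa_seq) >= identity_threshold
            if ok:
                clusters[ci].append(o.orf_id)
                placed = True
                break
        if not placed:
            reps.append(o.aa_seq)
            clusters.append([o.orf_id])
    return len(clusters), clusters


# ---------------------------------------------------------------------------
# Inventory assembly
# ---------------------------------------------------------------------------

def build_inventory(
    orfs: Sequence[Orf],
    hits: Mapping[str, Mapping[str, float]],
    registry: GeneFamilyRegistry,
    meta: SampleMeta,
    lineage_map: Optional[Mapping[str, str]] = None,
    identity_threshold: float = 1.0,
) -> SampleInventory:
    """Screen scored ORFs and tabulate variants by (lineage, gene).

    ``hits`` maps orf_id to its bit scores against every registry profile.
    Each ORF passes competitive decoy screening; accepted ORFs are grouped
    by lineage (``lineage_map`` on orf_id, then contig_id; unmapped ORFs
    become ``unclassified``) and gene, then de-replicated with
    :func:`count_variants`.  Rows with no accepted ORF are omitted.
    """
    meta.validate()
    lineage_map = lineage_map or {}
    groups: dict[tuple[str, str], list[Orf]] = {}
    for orf in orfs:
        scores = hits.get(orf.orf_id)
        if scores is None:
            continue
        gene = competitive_assign(scores, registry)
        if gene is None:
            continue
        lineage = lineage_map.get(orf.orf_id) or lineage_map.get(orf.contig_id) or UNCLASSIFIED
        groups.setdefault((lineage, gene), []).append(orf)
    rows = []
    for (lineage, gene) in sorted(groups):
        members = groups[(lineage, gene)]
        n, clusters = count_variants(members, identity_threshold)
        rows.append(InventoryRow(
            lineage=lineage,
            gene_symbol=gene,
            category=registry.category_of(gene),
            variant_count=n,
            orf_ids=sorted(o.orf_id for o in members),
        ))
    inv = SampleInventory(sample=meta, rows=rows)
    inv.validate()
    return inv


def category_scores(
    inventories: Sequence[SampleInventory],
    normalize: bool = False,
    categories: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Sample x category variant-count matrix.

    Scores sum ``variant_count`` over each category's rows; with
    ``normalize`` each sample row is divided by its total count (rows of
    all categories), giving proportions that sum to 1 for any sample with
    at least one row.
    """
    if not inventories:
        raise ValidationError("need at least one inventory")
    if categories is None:
        categories = sorted({r.category for inv in inventories for r in inv.rows})
    data = {}
    for inv in inventories:
        counts = dict.fromkeys(categories, 0)
        for r in inv.rows:
            if r.category in counts:
                counts[r.category] += r.variant_count
        data[inv.sample.sample_id] = counts
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(categories))
    df.index.name = "sample_id"
    if normalize:
        totals = df.sum(axis=1)
        df = df.div(totals.where(totals > 0, 1), axis=0)
    return df


def export_fig2_table(inventories: Sequence[SampleInventory]) -> pd.DataFrame:
    """The lineage x gene x sample inventory table.

    One row per inventory row, sorted by site, then depth ascending, then
    lineage, then gene; deterministic given identical inputs.
    """
    records = []
    for inv in inventories:
        m = inv.sample
        for r in inv.rows:
            records.append({
                "site": m.site,
                "depth_mbsf": m.depth_mbsf,
                "sulfate_status": m.sulfate_status,
                "lineage": r.lineage,
                "gene_symbol": r.gene_symbol,
                "category": r.category,
                "transcript_copies": r.variant_count,
            })
    df = pd.DataFrame.from_records(records, columns=FIG2_COLUMNS)
    df = df.sort_values(
        ["site", "depth_mbsf", "lineage", "gene_symbol"], kind="mergesort"
    ).reset_index(drop=True)
    return df


def fig2_table_to_tsv(df: pd.DataFrame) -> str:
    """Byte-stable TSV rendering of the inventory export."""
    lines = ["\t".join(FIG2_COLUMNS)]
    for _, row in df.iterrows():
        depth = f"{float(row.depth_mbsf):g}"
        lines.append(
            f"{row.site}\t{depth}\t{row.sulfate_status}\t{row.lineage}\t"
            f"{row.gene_symbol}\t{row.category}\t{int(row.transcript_copies)}"
        )
    return "\n".join(lines) + "\n"
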