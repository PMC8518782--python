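"""Orchestration: chain gene finding, scoring, screening and reporting.

The functions here are the library face of the command-line tool: build a
profile library from seed alignments, calibrate it against labelled
true/false homolog sequences, and scan per-sample contig sets into
marker-gene inventories.  They work on in-memory objects; the CLI adds
file I/O around them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .calibrate import LabeledScoreSet, derive_cutoffs
from .genefinder import Contig, Orf, six_frame_orfs
from .genie import (
    SampleInventory,
    SampleMeta,
    build_inventory,
    category_scores,
    export_fig2_table,
)
from .profilehmm import CutoffPair, HmmHit, ProfileHMM, build_from_alignment, viterbi_raw
from .registry import GeneFamilyRegistry

log = logging.getLogger("markergenie")


def build_hmm_library(
    alignments: Mapping[str, Sequence[str]],
    pseudocount: float = 1.0,
    match_fraction: float = 0.5,
) -> dict[str, ProfileHMM]:
    """Build one profile per named seed alignment."""
    return {
        name: build_from_alignment(
            list(seqs), pseudocount=pseudocount, match_fraction=match_fraction, name=name
        )
        for name, seqs in alignments.items()
    }


def score_sequences(
    hmm: ProfileHMM, seqs: Sequence[str]
) -> list[float]:
    """Raw best-local-alignment bit scores (finite, may be <= 0)."""
    return [viterbi_raw(hmm, s)[0] for s in seqs]


def calibrate_hmm(
    hmm: ProfileHMM,
    tp_seqs: Sequence[str],
    fp_seqs: Sequence[str] = (),
) -> tuple[CutoffPair, LabeledScoreSet]:
    """Score labelled sequences against a profile and derive its cutoffs."""
    scores = LabeledScoreSet(
        hmm_name=hmm.name,
        tp_scores=score_sequences(hmm, tp_seqs),
        fp_scores=score_sequences(hmm, fp_seqs),
    )
    cutoffs = derive_cutoffs(scores)
    if not cutoffs.separable:
        log.warning("%s: TP and FP scores overlap (separable=false)", hmm.name)
    return cutoffs, scores


def score_orfs(
    orfs: Sequence[Orf],
    hmms: Mapping[str, ProfileHMM],
) -> tuple[dict[str, dict[str, float]], list[HmmHit]]:
    """Score every ORF against every profile.

    Returns the raw bit-score matrix (every pair, scores may be <= 0)
    plus :class:`HmmHit` records for the positive-scoring pairs.
    """
    scores: dict[str, dict[str, float]] = {}
    hits: list[HmmHit] = []
    for orf in orfs:
        row: dict[str, float] = {}
        for name in sorted(hmms):
            s, s0, s1, n0, n1 = viterbi_raw(hmms[name], orf.aa_seq)
            row[name] = s
            if s > 0:
                hits.append(HmmHit(orf_id=orf.orf_id, hmm_name=name, bit_score=s,
                                   seq_start=s0, seq_end=s1, node_start=n0, node_end=n1))
        scores[orf.orf_id] = row
    return scores, hits


@dataclass
class ScanResult:
    """Everything one scan run produces."""

    orfs: dict[str, list[Orf]]  # per sample
    hits: dict[str, dict[str, dict[str, float]]]  # sample -> orf -> hmm -> score
    hit_records: dict[str, list[HmmHit]]  # per sample, positive scores only
    inventories: list[SampleInventory]
    fig2: pd.DataFrame
    categories: pd.DataFrame


def scan_samples(
    contigs_by_sample: Mapping[str, Sequence[Contig]],
    hmms: Mapping[str, ProfileHMM],
    registry: GeneFamilyRegistry,
    metas: Mapping[str, SampleMeta],
    lineage_map: Optional[Mapping[str, str]] = None,
    min_aa_len: int = 30,
    identity_threshold: float = 1.0,
    normalize: bool = False,
) -> ScanResult:
    """Run the full per-sample pipeline and assemble the inventory export.

    For every sample: extract six-frame ORFs, score each against every
    registry profile, screen competitively against decoys and gathering
    cutoffs, group accepted ORFs by lineage and gene, and de-replicate
    into variant counts.
    """
    # make calibrated cutoffs carried on the profiles visible to the registry
    for name in registry.target_hmm_names():
        hmm = hmms.get(name)
        if hmm is not None and hmm.cutoffs is not None and registry.gathering(name) is None:
            registry.attach_cutoffs(name, hmm.cutoffs)
    needed = {n: hmms[n] for n in registry.all_hmm_names() if n in hmms}
    missing = set(registry.all_hmm_names()) - set(needed)
    if missing:
        from .errors import ConfigurationError
        raise ConfigurationError(f"registry profiles without HMM files: {sorted(missing)}")

    all_orfs: dict[str, list[Orf]] = {}
    all_hits: dict[str, dict[str, dict[str, float]]] = {}
    all_hit_records: dict[str, list[HmmHit]] = {}
    inventories: list[SampleInventory] = []
    for sid in sorted(contigs_by_sample):
        meta = metas[sid]
        if meta.sample_id != sid:
            from .errors import ValidationError
            raise ValidationError(f"metadata sample_id {meta.sample_id!r} != {sid!r}")
        orfs: list[Orf] = []
        for contig in contigs_by_sample[sid]:
            orfs.extend(six_frame_orfs(contig, min_aa_len=min_aa_len))
        scores, hit_records = score_orfs(orfs, needed)
        inventories.append(build_inventory(
            orfs, scores, registry, meta,
            lineage_map=lineage_map, identity_threshold=identity_threshold,
        ))
        all_orfs[sid] = orfs
        all_hits[sid] = scores
        all_hit_records[sid] = hit_records
        log.info("%s: %d contigs, %d ORFs, %d inventory rows",
                 sid, len(contigs_by_sample[sid]), len(orfs), len(inventories[-1].rows))
    fig2 = export_fig2_table(inventories)
    cats = category_scores(inventories, normalize=normalize,
                           categories=registry.categories())
    return ScanResult(orfs=all_orfs, hits=all_hits, hit_records=all_hit_records,
                      inventories=inventories, fig2=fig2, categories=cats)


def run_synthetic_study(
    dataset,
    pseudocount: float = 1.0,
    match_fraction: float = 0.5,
    min_aa_len: Optional[int] = None,
    identity_threshold: float = 1.0,
):
    """Build, calibrate and scan a :class:`~markergenie.synthdata.SyntheticDataset`.

    Convenience wrapper used by the demo, the test-suite and the
    acceptance checks: builds one profile per family from its seed
    alignment, calibrates every target profile against the dataset's
    labelled members, and scans all samples.  Returns
    ``(result, hmms, registry)``.
    """
    from io import StringIO

    from .registry import parse_registry_tsv

    plan = dataset.plan
    alignments = {fid: fam.seed_members for fid, fam in dataset.families.items()}
    hmms = build_hmm_library(alignments, pseudocount=pseudocount,
                             match_fraction=match_fraction)
    registry = parse_registry_tsv(StringIO(dataset.registry_tsv()))
    decoy_fp = [m for d in sorted(plan.decoy_families)
                for m in dataset.families[d].calib_members]
    for gene in sorted(plan.gene_categories):
        cutoffs, _ = calibrate_hmm(
            hmms[gene], dataset.families[gene].calib_members, decoy_fp
        )
        hmms[gene] = hmms[gene].with_cutoffs(cutoffs)
    result = scan_samples(
        contigs_by_sample=dataset.contigs,
        hmms=hmms,
        registry=registry,
        metas={m.sample_id: m for m in dataset.metas},
        lineage_map=dataset.lineage_map,
        min_aa_len=min_aa_len if min_aa_len is not None else plan.min_aa_len,
        identity_threshold=identity_threshold,
    )
    return result, hmms, registry
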