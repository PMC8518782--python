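"""Bit-score cutoff calibration and competitive decoy screening.

Each marker-gene profile is calibrated from two labelled score sets:
scores of curated true family members (TP) and of curated non-target
homologs (FP).  The *trusted* cutoff is the lowest TP score, the *noise*
cutoff the highest FP score, and the operational *gathering* cutoff sits
midway between them when the two sets separate cleanly.

Screening is competitive: every candidate ORF is scored against all
target *and* decoy profiles in the registry, and a hit is only accepted
when (a) the best-scoring profile is a target, not a decoy model of a
confounding homolog family, and (b) the score clears that target's
gathering cutoff.  Decoy competition rejects contaminant homologs that
would otherwise creep over a fixed threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .errors import ConfigurationError, ValidationError
from .profilehmm import CutoffPair
from .registry import GeneFamilyRegistry

__all__ = [
    "CutoffPair",
    "LabeledScoreSet",
    "derive_cutoffs",
    "competitive_assign",
    "calibration_report_tsv",
]


@dataclass
class LabeledScoreSet:
    """Curated true/false homolog bit scores for one profile."""

    hmm_name: str
    tp_scores: Sequence[float]
    fp_scores: Sequence[float] = ()

    def validate(self) -> None:
        if not self.tp_scores:
            raise ValidationError(f"{self.hmm_name}: tp_scores must be non-empty")
        for s in list(self.tp_scores) + list(self.fp_scores):
            if not math.isfinite(s):
                raise ValidationError(f"{self.hmm_name}: scores must be finite, got {s}")


def derive_cutoffs(scores: LabeledScoreSet) -> CutoffPair:
    """Derive trusted/noise/gathering cutoffs from labelled scores.

    When the sets separate (``min(tp) > max(fp)``) the gathering cutoff is
    the midpoint of the separation gap (or the trusted cutoff itself when
    there are no FP scores).  Otherwise the sets overlap: ``separable``
    is False and the gathering cutoff is the threshold maximising
    classification accuracy over the labelled scores, ties broken toward
    the larger threshold.  Permutation-invariant in both inputs.
    """
    scores.validate()
    trusted = min(scores.tp_scores)
    noise = max(scores.fp_scores) if scores.fp_scores else -math.inf
    if trusted > noise:
        gathering = trusted if not scores.fp_scores else (trusted + noise) / 2.0
        pair = CutoffPair(trusted=trusted, noise=noise, gathering=gathering, separable=True)
    else:
        candidates = sorted(set(scores.tp_scores) | set(scores.fp_scores))
        candidates.append(candidates[-1] + 1.0)  # "reject everything"
        best_t, best_acc = None, -1
        for t in candidates:
            acc = sum(1 for s in scores.tp_scores if s >= t) + \
                sum(1 for s in scores.fp_scores if s < t)
            if acc >= best_acc:  # >= : ties broken toward larger threshold
                best_acc, best_t = acc, t
        pair = CutoffPair(trusted=trusted, noise=noise, gathering=float(best_t),
                          separable=False)
    pair.validate()
    return pair


def competitive_assign(
    orf_scores: Mapping[str, float],
    registry: GeneFamilyRegistry,
) -> Optional[str]:
    """Best-model competition of one ORF against all registry profiles.

    ``orf_scores`` must contain a bit score for every target and decoy
    profile in the registry.  Returns the accepted gene symbol, or
    ``None`` when the best model is a decoy or the best target score
    falls below its gathering cutoff (ties at the cutoff are accepted).
    Score ties are resolved conservatively: a decoy beats a target;
    among targets the lexicographically smallest profile name wins.
    """
    targets = registry.target_hmm_names()
    decoys = registry.decoy_hmm_names()
    missing = [h for h in list(targets) + list(decoys) if h not in orf_scores]
    if missing:
        raise ValidationError(f"orf_scores missing registry profiles: {missing}")
    best_name, best_key = None, None
    for name in sorted(targets) + sorted(decoys):
        s = orf_scores[name]
        is_decoy = name in decoys
        # sort key: higher score wins; on ties decoys win; then lexicographic
        key = (s, 1 if is_decoy else 0, [-ord(c) for c in name])
        if best_key is None or key > best_key:
            best_name, best_key = name, key
    if best_name in decoys:
        return None
    gathering = registry.gathering(best_name)
    if gathering is None:
        raise ConfigurationError(f"target profile {best_name!r} has no cutoffs")
    if orf_scores[best_name] >= gathering:
        return registry.gene_of(best_name)
    return None


def calibration_report_tsv(rows: Sequence[tuple[str, CutoffPair, int, int]]) -> str:
    """Render the calibration report: one row per calibrated profile."""
    out = ["hmm_name\ttrusted\tnoise\tgathering\tseparable\tn_tp\tn_fp"]
    for name, c, n_tp, n_fp in rows:
        noise = f"{c.noise:.4f}" if math.isfinite(c.noise) else "-inf"
        out.append(
            f"{name}\t{c.trusted:.4f}\t{noise}\t{c.gathering:.4f}\t"
            f"{str(c.separable).lower()}\t{n_tp}\t{n_fp}"
        )
    return "\n".join(out) + "\n"
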