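"""The gene-family registry: gene symbol -> process category -> profiles.

The registry is the single configuration object tying marker genes to
the biogeochemical process they diagnose and to the profile HMMs (target
and decoy) used to detect them.  The built-in category vocabulary covers
the lithotrophic energy metabolisms and ROS-neutralization systems the
tool inventories; extra categories can be admitted per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

from .errors import ConfigurationError, ValidationError
from .profilehmm import CutoffPair

ENERGY_CATEGORIES = (
    "iron_oxidation",
    "sulfur_oxidation",
    "nitrate_reduction",
    "arsenate_reduction",
    "selenate_reduction",
    "sulfite_reduction",
)
ROS_CATEGORIES = (
    "catalase",
    "peroxiredoxin",
    "superoxide_dismutase",
    "hydroperoxide_reductase",
    "dyp_peroxidase",
    "heme_peroxidase",
)
DEFAULT_CATEGORIES = ENERGY_CATEGORIES + ROS_CATEGORIES
DECOY_CATEGORY = "decoy"


@dataclass
class RegistryEntry:
    gene_symbol: str
    category: str
    target_hmm_names: list[str] = field(default_factory=list)
    decoy_hmm_names: list[str] = field(default_factory=list)


class GeneFamilyRegistry:
    """Mapping of marker genes to categories and target/decoy profiles."""

    def __init__(
        self,
        entries: Iterable[RegistryEntry],
        extra_categories: Iterable[str] = (),
    ) -> None:
        self.entries: list[RegistryEntry] = list(entries)
        vocab = set(DEFAULT_CATEGORIES) | set(extra_categories)
        seen_genes: set[str] = set()
        self._target_gene: dict[str, str] = {}
        self._decoys: set[str] = set()
        self._overrides: dict[str, float] = {}
        self._cutoffs: dict[str, CutoffPair] = {}
        for e in self.entries:
            if e.gene_symbol in seen_genes:
                raise ValidationError(f"duplicate gene_symbol {e.gene_symbol!r}")
            seen_genes.add(e.gene_symbol)
            if e.category not in vocab:
                raise ValidationError(
                    f"{e.gene_symbol}: unknown category {e.category!r} "
                    f"(pass extra_categories to extend the vocabulary)"
                )
            for h in e.target_hmm_names:
                if h in self._target_gene:
                    raise ValidationError(f"target profile {h!r} referenced twice")
                self._target_gene[h] = e.gene_symbol
            self._decoys.update(e.decoy_hmm_names)
        overlap = set(self._target_gene) & self._decoys
        if overlap:
            raise ValidationError(f"profiles listed as both target and decoy: {sorted(overlap)}")
        self._category = {e.gene_symbol: e.category for e in self.entries}

    # -- queries ----------------------------------------------------------
    def target_hmm_names(self) -> list[str]:
        return sorted(self._target_gene)

    def decoy_hmm_names(self) -> list[str]:
        return sorted(self._decoys)

    def all_hmm_names(self) -> list[str]:
        return self.target_hmm_names() + self.decoy_hmm_names()

    def gene_of(self, hmm_name: str) -> str:
        return self._target_gene[hmm_name]

    def category_of(self, gene_symbol: str) -> str:
        return self._category[gene_symbol]

    def categories(self) -> list[str]:
        return sorted({e.category for e in self.entries})

    def gathering(self, hmm_name: str) -> Optional[float]:
        """Gathering cutoff for a target profile: override, else calibration."""
        if hmm_name in self._overrides:
            return self._overrides[hmm_name]
        c = self._cutoffs.get(hmm_name)
        return c.gathering if c is not None else None

    # -- mutation ---------------------------------------------------------
    def set_override(self, hmm_name: str, gathering: float) -> None:
        if hmm_name not in self._target_gene:
            raise ConfigurationError(f"override for unknown target profile {hmm_name!r}")
        self._overrides[hmm_name] = gathering

    def attach_cutoffs(self, hmm_name: str, cutoffs: CutoffPair) -> None:
        if hmm_name not in self._target_gene:
            raise ConfigurationError(f"cutoffs for unknown target profile {hmm_name!r}")
        self._cutoffs[hmm_name] = cutoffs

    def subset(self, categories: Iterable[str]) -> "GeneFamilyRegistry":
        """Restrict to entries of the given categories (decoys are kept)."""
        keep = set(categories)
        entries = [e for e in self.entries if e.category in keep]
        decoys = sorted({h for e in self.entries for h in e.decoy_hmm_names})
        if entries and decoys and not any(e.decoy_hmm_names for e in entries):
            entries[0].decoy_hmm_names = decoys
        sub = GeneFamilyRegistry(entries, extra_categories={e.category for e in entries})
        for h, g in self._overrides.items():
            if h in sub._target_gene:
                sub.set_override(h, g)
        for h, c in self._cutoffs.items():
            if h in sub._target_gene:
                sub.attach_cutoffs(h, c)
        return sub


def parse_registry_tsv(stream: TextIO, extra_categories: Iterable[str] = ()) -> GeneFamilyRegistry:
    """Read the registry table.

    Columns: ``gene_symbol  category  hmm_file  role  [gathering_override]``
    with ``role`` in {target, decoy}.  The profile name is the ``hmm_file``
    stem.  Decoy rows use category ``decoy`` and their gene_symbol names
    the confounding family.  Decoy profiles compete globally.
    """
    header: Optional[list[str]] = None
    by_gene: dict[str, RegistryEntry] = {}
    decoys: list[str] = []
    overrides: dict[str, float] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            expected = ["gene_symbol", "category", "hmm_file", "role"]
            if [h.strip() for h in parts[:4]] != expected:
                raise ValidationError(f"registry header must start with {expected}, got {parts}")
            continue
        if len(parts) < 4:
            raise ValidationError(f"registry row has fewer than 4 columns: {line!r}")
        gene, category, hmm_file, role = (p.strip() for p in parts[:4])
        hmm_name = hmm_file.rsplit("/", 1)[-1]
        hmm_name = hmm_name[:-4] if hmm_name.endswith(".hmm") else hmm_name
        if role == "decoy":
            decoys.append(hmm_name)
            continue
        if role != "target":
            raise ValidationError(f"unknown role {role!r} in registry row: {line!r}")
        entry = by_gene.setdefault(gene, RegistryEntry(gene_symbol=gene, category=category))
        if entry.category != category:
            raise ValidationError(f"gene {gene!r} listed with two categories")
        entry.target_hmm_names.append(hmm_name)
        if len(parts) > 4 and parts[4].strip():
            overrides[hmm_name] = float(parts[4])
    entries = list(by_gene.values())
    if entries:
        entries[0].decoy_hmm_names = sorted(set(decoys))
    reg = GeneFamilyRegistry(entries, extra_categories=extra_categories)
    for h, g in overrides.items():
        reg.set_override(h, g)
    return reg


def registry_to_tsv(reg: GeneFamilyRegistry) -> str:
    lines = ["gene_symbol\tcategory\thmm_file\trole\tgathering_override"]
    for e in reg.entries:
        for h in e.target_hmm_names:
            ov = reg._overrides.get(h)
            ov_s = "" if ov is None or not math.isfinite(ov) else f"{ov:.4f}"
            lines.append(f"{e.gene_symbol}\t{e.category}\t{h}.hmm\ttarget\t{ov_s}")
    for h in reg.decoy_hmm_names():
        lines.append(f"{h}\t{DECOY_CATEGORY}\t{h}.hmm\tdecoy\t")
    return "\n".join(lines) + "\n"
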