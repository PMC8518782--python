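"""Deterministic synthetic benchmark data with a machine-readable truth.

The generator emulates, at toy scale, the statistical structure of the
sedimentary metatranscriptome assemblies the tool targets: per-sample
contig sets containing planted marker-gene ORFs from simulated protein
families attributed to named taxa, decoy ORFs from confounding homolog
families, and ORF-free random background contigs.  Every planted feature
is recorded in a truth table, so detection, calibration, screening and
quantification can all be validated offline and exactly.

Family evolution is substitution-only (no indels): members derive from a
random root by independent per-site substitution.  This keeps pairwise
identities closed-form (binomial) and lets family members double as a
trivially aligned seed alignment.  Decoy families can be anchored to a
target family's root at a stated fraction of shared sites, which makes
cutoff calibration genuinely discriminative rather than trivial.

A single global seed fans out to per-family and per-sample subseeds by
stable hashing of identifiers, so adding a sample or family never
perturbs the data generated for existing ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .genefinder import Contig, revcomp, six_frame_orfs, translate
from .genie import SampleMeta
from .profilehmm import AMINO_ACIDS

from Bio.Data import CodonTable

#: members of each family are partitioned into these roles, in order
SEED_N = 12        # seed-alignment members (HMM construction)
CALIB_N = 20       # labelled calibration members (TP, or FP when decoy)
HELDOUT_N = 20     # held-out members for cutoff evaluation

STOP_CODONS = ("TAA", "TAG", "TGA")
# AT-rich background makes stop codons frequent on both strands, keeping
# random contigs free of spurious ORFs with high probability
_BG_NT = "ACGT"
_BG_P = (0.40, 0.10, 0.10, 0.40)


def stable_seed(seed: int, *tags: object) -> int:
    """Derive a deterministic subseed (< 2^31) from a seed and tags."""
    h = hashlib.sha256("|".join([str(seed), *map(str, tags)]).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class FamilySpec:
    """Parameters of one simulated protein family.

    ``anchor_family``/``shared_fraction`` turn the family into a decoy
    constrained to share that fraction of root sites with the anchor
    target family's root.
    """

    family_id: str
    root_length: int = 150
    n_members: int = 60
    substitution_rate: float = 0.05
    seed: int = 0
    anchor_family: Optional[str] = None
    shared_fraction: float = 0.0

    def validate(self) -> None:
        if not (0 <= self.substitution_rate < 1):
            raise ValidationError(f"{self.family_id}: substitution_rate out of [0, 1)")
        if self.n_members < 1:
            raise ValidationError(f"{self.family_id}: n_members must be >= 1")
        if self.root_length < 30:
            raise ValidationError(f"{self.family_id}: root_length must be >= 30")
        if not (0 <= self.shared_fraction <= 1):
            raise ValidationError(f"{self.family_id}: shared_fraction out of [0, 1]")


@dataclass
class Plant:
    gene_symbol: str
    lineage: str
    n_variants: int


@dataclass
class SamplePlan:
    meta: SampleMeta
    plants: list[Plant] = field(default_factory=list)
    n_decoy_orfs: int = 8
    n_random_contigs: int = 50


@dataclass
class PlantPlan:
    """What to plant where: the full blueprint of a synthetic study."""

    samples: list[SamplePlan]
    gene_categories: dict[str, str]
    decoy_families: list[str] = field(default_factory=list)
    min_aa_len: int = 30

    def validate(self, family_ids: set[str]) -> None:
        for sp in self.samples:
            sp.meta.validate()
            for p in sp.plants:
                if p.n_variants < 1:
                    raise ValidationError(f"{p.gene_symbol}: n_variants must be >= 1")
                if p.gene_symbol not in family_ids:
                    raise ValidationError(f"planted gene {p.gene_symbol!r} has no family spec")
                if p.gene_symbol not in self.gene_categories:
                    raise ValidationError(f"planted gene {p.gene_symbol!r} has no category")
        for d in self.decoy_families:
            if d not in family_ids:
                raise ValidationError(f"decoy family {d!r} has no family spec")


@dataclass
class PlantedOrf:
    sample_id: str
    contig_id: str
    gene_symbol: str
    lineage: str
    strand: str
    nt_start: int
    nt_end: int
    aa_seq: str


@dataclass
class TruthTable:
    """Planted ground truth: per-sample counts plus ORF coordinates."""

    rows: list[tuple[str, str, str, int]]  # sample_id, lineage, gene, variant_count
    planted: list[PlantedOrf]

    def to_tsv(self) -> str:
        lines = ["sample_id\tlineage\tgene_symbol\tvariant_count"]
        for r in self.rows:
            lines.append("\t".join(map(str, r)))
        return "\n".join(lines) + "\n"

    def planted_to_tsv(self) -> str:
        lines = ["sample_id\tcontig_id\tgene_symbol\tlineage\tstrand\tnt_start\tnt_end\taa_seq"]
        for p in self.planted:
            lines.append(
                f"{p.sample_id}\t{p.contig_id}\t{p.gene_symbol}\t{p.lineage}\t"
                f"{p.strand}\t{p.nt_start}\t{p.nt_end}\t{p.aa_seq}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Family evolution
# ---------------------------------------------------------------------------

def _random_root(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(root: str, rate: float, rng: np.random.Generator) -> str:
    out = list(root)
    hit = rng.random(len(root)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def evolve_family(
    spec: FamilySpec,
    anchor_root: Optional[str] = None,
) -> tuple[str, list[str]]:
    """Simulate a protein family: a root and ``n_members`` descendants.

    The root is uniform over the 20-letter alphabet, unless
    ``anchor_root`` is given, in which case ``shared_fraction`` of its
    sites (chosen at random) are copied into an otherwise random root.
    Each member substitutes every site independently with probability
    ``substitution_rate`` to a uniformly chosen *different* residue.
    Fully deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    root = _random_root(spec.root_length, rng)
    if anchor_root is not None:
        if len(anchor_root) != spec.root_length:
            raise ValidationError(
                f"{spec.family_id}: anchor root length {len(anchor_root)} "
                f"!= root_length {spec.root_length}"
            )
        n_shared = int(round(spec.shared_fraction * spec.root_length))
        idx = rng.choice(spec.root_length, size=n_shared, replace=False)
        root = list(root)
        for i in idx:
            root[i] = anchor_root[i]
        root = "".join(root)
    members = [_mutate(root, spec.substitution_rate, rng) for _ in range(spec.n_members)]
    return root, members


# ---------------------------------------------------------------------------
# Nucleotide-level construction
# ---------------------------------------------------------------------------

def _codons_for(table_id: int = 11) -> dict[str, list[str]]:
    tbl = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(tbl.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa


_CODONS_BY_AA = _codons_for()


def reverse_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Uniform synonymous-codon reverse translation (table 11)."""
    codons = []
    for aa in aa_seq:
        opts = _CODONS_BY_AA[aa]
        codons.append(opts[rng.integers(len(opts))])
    return "".join(codons)


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BG_NT), size=n, p=list(_BG_P)))


def _flank(n: int, rng: np.random.Generator, stop_first: bool) -> str:
    """AT-rich junk of length n with a forced stop codon at the ORF edge."""
    junk = _random_nt(n - 3, rng)
    stop = STOP_CODONS[rng.integers(3)]
    return stop + junk if stop_first else junk + stop


def _planted_contig(
    contig_id: str, sample_id: str, aa_seq: str, rng: np.random.Generator,
) -> tuple[Contig, str, int, int]:
    """Embed one ORF in stop-bracketed random flanks on a random strand."""
    orf_nt = reverse_translate(aa_seq, rng)
    left_len = 33 + 3 * int(rng.integers(0, 20))  # in-frame stop right before ORF
    right_len = 33 + int(rng.integers(0, 58))
    left = _flank(left_len, rng, stop_first=False)
    right = _flank(right_len, rng, stop_first=True)
    seq = left + orf_nt + right
    s, e = len(left), len(left) + len(orf_nt)
    strand = "+"
    if rng.random() < 0.5:
        seq = revcomp(seq)
        s, e = len(seq) - e, len(seq) - s
        strand = "-"
    return Contig(contig_id=contig_id, sample_id=sample_id, seq=seq), strand, s, e


def _noise_contig(
    contig_id: str, sample_id: str, rng: np.random.Generator, min_aa_len: int,
    max_tries: int = 500,
) -> Contig:
    """A random contig guaranteed to contain no ORF of min_aa_len in any frame."""
    for _ in range(max_tries):
        n = int(rng.integers(150, 451))
        c = Contig(contig_id=contig_id, sample_id=sample_id, seq=_random_nt(n, rng))
        if not six_frame_orfs(c, min_aa_len=min_aa_len):
            return c
    raise ValidationError(f"{contig_id}: could not generate an ORF-free contig")


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class Family:
    spec: FamilySpec
    root: str
    members: list[str]

    @property
    def seed_members(self) -> list[str]:
        return self.members[:SEED_N]

    @property
    def calib_members(self) -> list[str]:
        return self.members[SEED_N:SEED_N + CALIB_N]

    @property
    def heldout_members(self) -> list[str]:
        return self.members[SEED_N + CALIB_N:SEED_N + CALIB_N + HELDOUT_N]

    @property
    def plant_pool(self) -> list[str]:
        pool = self.members[SEED_N + CALIB_N + HELDOUT_N:]
        seen: set[str] = set()
        out = []
        for m in pool:
            if m not in seen:
                seen.add(m)
                out.append(m)
        return out


@dataclass
class SyntheticDataset:
    """Everything :func:`make_dataset` produces, with text writers."""

    plan: PlantPlan
    contigs: dict[str, list[Contig]]  # sample_id -> contigs
    truth: TruthTable
    lineage_map: dict[str, str]  # contig_id -> lineage
    families: dict[str, Family]
    metas: list[SampleMeta]

    def seed_alignment(self, family_id: str) -> list[str]:
        return self.families[family_id].seed_members

    def registry_tsv(self) -> str:
        lines = ["gene_symbol\tcategory\thmm_file\trole\tgathering_override"]
        for gene, cat in sorted(self.plan.gene_categories.items()):
            lines.append(f"{gene}\t{cat}\t{gene}.hmm\ttarget\t")
        for d in sorted(self.plan.decoy_families):
            lines.append(f"{d}\tdecoy\t{d}.hmm\tdecoy\t")
        return "\n".join(lines) + "\n"

    def lineage_map_tsv(self) -> str:
        lines = ["id\tlineage"]
        for cid in sorted(self.lineage_map):
            lines.append(f"{cid}\t{self.lineage_map[cid]}")
        return "\n".join(lines) + "\n"

    def metadata_tsv(self) -> str:
        lines = ["sample_id\tsite\tdepth_mbsf\tsulfate_status"]
        for m in self.metas:
            lines.append(f"{m.sample_id}\t{m.site}\t{m.depth_mbsf:g}\t{m.sulfate_status}")
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        (out / "samples").mkdir(parents=True, exist_ok=True)
        (out / "seed_alignments").mkdir(exist_ok=True)
        (out / "calibration").mkdir(exist_ok=True)
        for sid, contigs in self.contigs.items():
            with open(out / "samples" / f"{sid}.contigs.fna", "w") as fh:
                for c in contigs:
                    fh.write(f">{c.contig_id}\n{c.seq}\n")
        for fid, fam in self.families.items():
            with open(out / "seed_alignments" / f"{fid}.afa", "w") as fh:
                for i, m in enumerate(fam.seed_members):
                    fh.write(f">{fid}_seed{i + 1}\n{m}\n")
        decoy_fp = [m for d in sorted(self.plan.decoy_families)
                    for m in self.families[d].calib_members]
        for gene in sorted(self.plan.gene_categories):
            fam = self.families[gene]
            with open(out / "calibration" / f"{gene}.tp.faa", "w") as fh:
                for i, m in enumerate(fam.calib_members):
                    fh.write(f">{gene}_tp{i + 1}\n{m}\n")
            with open(out / "calibration" / f"{gene}.fp.faa", "w") as fh:
                for i, m in enumerate(decoy_fp):
                    fh.write(f">{gene}_fp{i + 1}\n{m}\n")
        (out / "registry.tsv").write_text(self.registry_tsv())
        (out / "lineage_map.tsv").write_text(self.lineage_map_tsv())
        (out / "sample_metadata.tsv").write_text(self.metadata_tsv())
        (out / "truth_table.tsv").write_text(self.truth.to_tsv())
        (out / "planted_orfs.tsv").write_text(self.truth.planted_to_tsv())


def make_dataset(
    plan: PlantPlan,
    family_specs: Mapping[str, FamilySpec],
    seed: int,
) -> SyntheticDataset:
    """Generate the full synthetic study described by ``plan``.

    Families are evolved from per-family subseeds; each planted variant
    is reverse-translated, embedded between stop-bracketed random flanks
    (>= 30 nt) on a random strand, and recorded in the truth table.
    Random contigs are rejection-sampled to contain no ORF of the plan's
    minimum length in any frame.  Deterministic given ``seed``.
    """
    plan.validate(set(family_specs))
    # evolve targets first so decoys can anchor to their roots
    families: dict[str, Family] = {}
    ordered = sorted(family_specs, key=lambda f: family_specs[f].anchor_family is not None)
    for fid in ordered:
        spec = family_specs[fid]
        if spec.seed == 0:
            spec = FamilySpec(**{**spec.__dict__, "seed": stable_seed(seed, "family", fid)})
        anchor = None
        if spec.anchor_family is not None:
            if spec.anchor_family not in families:
                raise ValidationError(
                    f"{fid}: anchor family {spec.anchor_family!r} missing or itself anchored"
                )
            anchor = families[spec.anchor_family].root
        root, members = evolve_family(spec, anchor_root=anchor)
        families[fid] = Family(spec=spec, root=root, members=members)

    contigs: dict[str, list[Contig]] = {}
    planted: list[PlantedOrf] = []
    lineage_map: dict[str, str] = {}
    truth_rows: list[tuple[str, str, str, int]] = []
    decoy_lineage_cycle = sorted({p.lineage for sp in plan.samples for p in sp.plants}) or ["unknown"]

    for sp in plan.samples:
        sid = sp.meta.sample_id
        rng = np.random.default_rng(stable_seed(seed, "sample", sid))
        sample_contigs: list[Contig] = []
        counter = 0

        def next_id() -> str:
            nonlocal counter
            counter += 1
            return f"{sid}_c{counter:04d}"

        for p in sp.plants:
            pool = families[p.gene_symbol].plant_pool
            if len(pool) < p.n_variants:
                raise ValidationError(
                    f"{sid}/{p.gene_symbol}: plant pool has {len(pool)} distinct "
                    f"members, need {p.n_variants}"
                )
            idx = rng.choice(len(pool), size=p.n_variants, replace=False)
            for i in sorted(int(j) for j in idx):
                cid = next_id()
                contig, strand, s, e = _planted_contig(cid, sid, pool[i], rng)
                contig.validate()
                sample_contigs.append(contig)
                lineage_map[cid] = p.lineage
                planted.append(PlantedOrf(
                    sample_id=sid, contig_id=cid, gene_symbol=p.gene_symbol,
                    lineage=p.lineage, strand=strand, nt_start=s, nt_end=e,
                    aa_seq=pool[i],
                ))
            truth_rows.append((sid, p.lineage, p.gene_symbol, p.n_variants))
        decoy_ids = sorted(plan.decoy_families)
        for k in range(sp.n_decoy_orfs):
            fam = families[decoy_ids[k % len(decoy_ids)]] if decoy_ids else None
            if fam is None:
                break
            pool = fam.plant_pool
            aa = pool[int(rng.integers(len(pool)))]
            cid = next_id()
            contig, _, _, _ = _planted_contig(cid, sid, aa, rng)
            sample_contigs.append(contig)
            lineage_map[cid] = decoy_lineage_cycle[k % len(decoy_lineage_cycle)]
        for _ in range(sp.n_random_contigs):
            sample_contigs.append(_noise_contig(next_id(), sid, rng, plan.min_aa_len))
        contigs[sid] = sample_contigs

    truth_rows.sort()
    truth = TruthTable(rows=truth_rows, planted=planted)
    return SyntheticDataset(
        plan=plan, contigs=contigs, truth=truth, lineage_map=lineage_map,
        families=families, metas=[sp.meta for sp in plan.samples],
    )


# ---------------------------------------------------------------------------
# The demo study: 3 samples, 6 marker genes, 2 decoy families
# ---------------------------------------------------------------------------

DEMO_GENE_CATEGORIES = {
    "cyc2": "iron_oxidation",
    "sdo": "sulfur_oxidation",
    "sqr": "sulfur_oxidation",
    "narG": "nitrate_reduction",
    "katG": "catalase",
    "sodA": "superoxide_dismutase",
}
DEMO_DECOYS = ["cyc2_paralog", "katG_paralog"]


def demo_family_specs(root_length: int = 150, n_members: int = 60) -> dict[str, FamilySpec]:
    """Family specs for the demo study (seeds filled in by make_dataset)."""
    specs = {
        g: FamilySpec(family_id=g, root_length=root_length, n_members=n_members)
        for g in DEMO_GENE_CATEGORIES
    }
    specs["cyc2_paralog"] = FamilySpec(
        family_id="cyc2_paralog", root_length=root_length, n_members=n_members,
        anchor_family="cyc2", shared_fraction=0.4,
    )
    specs["katG_paralog"] = FamilySpec(
        family_id="katG_paralog", root_length=root_length, n_members=n_members,
        anchor_family="katG", shared_fraction=0.4,
    )
    return specs


def demo_plan(n_random_contigs: int = 50, n_decoy_orfs: int = 8) -> PlantPlan:
    """Three samples mirroring the study layout: two sulfate-depleted
    Baltic Sea sites and one deep Peru Margin sample where nitrate
    reduction (narG) is planted exclusively."""
    samples = [
        SamplePlan(
            meta=SampleMeta("M0059E_12", "M0059E", 12.0, "depleted"),
            plants=[
                Plant("sdo", "Chloroflexi", 2),
                Plant("sqr", "Firmicutes", 1),
                Plant("sodA", "Firmicutes", 2),
                Plant("katG", "Chloroflexi", 1),
            ],
            n_decoy_orfs=n_decoy_orfs, n_random_contigs=n_random_contigs,
        ),
        SamplePlan(
            meta=SampleMeta("M0063E_42", "M0063E", 42.0, "depleted"),
            plants=[
                Plant("sdo", "Firmicutes", 1),
                Plant("sqr", "Chloroflexi", 2),
                Plant("katG", "Chloroflexi", 2),
                Plant("sodA", "Deltaproteobacteria", 1),
            ],
            n_decoy_orfs=n_decoy_orfs, n_random_contigs=n_random_contigs,
        ),
        SamplePlan(
            meta=SampleMeta("1229D_91", "1229D", 91.0, "present"),
            plants=[
                Plant("cyc2", "Gammaproteobacteria", 2),
                Plant("narG", "Gammaproteobacteria", 1),
                Plant("katG", "Alphaproteobacteria", 3),
                Plant("sdo", "Actinobacteria", 1),
            ],
            n_decoy_orfs=n_decoy_orfs, n_random_contigs=n_random_contigs,
        ),
    ]
    return PlantPlan(
        samples=samples,
        gene_categories=dict(DEMO_GENE_CATEGORIES),
        decoy_families=list(DEMO_DECOYS),
    )


def demo_dataset(seed: int = 42, **plan_kwargs) -> SyntheticDataset:
    return make_dataset(demo_plan(**plan_kwargs), demo_family_specs(), seed)


def plan_from_dict(d: dict) -> tuple[PlantPlan, dict[str, FamilySpec]]:
    """Build a plan + family specs from a JSON-style dictionary."""
    samples = []
    for s in d["samples"]:
        samples.append(SamplePlan(
            meta=SampleMeta(s["sample_id"], s["site"], float(s["depth_mbsf"]),
                            s["sulfate_status"]),
            plants=[Plant(*p) for p in s.get("plants", [])],
            n_decoy_orfs=int(s.get("n_decoy_orfs", 8)),
            n_random_contigs=int(s.get("n_random_contigs", 50)),
        ))
    plan = PlantPlan(
        samples=samples,
        gene_categories=dict(d["gene_categories"]),
        decoy_families=list(d.get("decoy_families", [])),
        min_aa_len=int(d.get("min_aa_len", 30)),
    )
    specs = {}
    for fid, f in d.get("families", {}).items():
        specs[fid] = FamilySpec(
            family_id=fid,
            root_length=int(f.get("root_length", 150)),
            n_members=int(f.get("n_members", 60)),
            substitution_rate=float(f.get("substitution_rate", 0.05)),
            seed=int(f.get("seed", 0)),
            anchor_family=f.get("anchor_family"),
            shared_fraction=float(f.get("shared_fraction", 0.0)),
        )
    return plan, specs
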