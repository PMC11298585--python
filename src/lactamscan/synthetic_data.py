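"""Seeded generators for every input class the pipeline consumes.

Sequence side: NRPS gene variants derived from the bundled synthetic SulM
reference with screening features planted or ablated (Gln-Cys-Asn motif,
aspartate at position I/II, number of cationic active-site residues, DAP
specificity code, sulfotransferase gene), plus whole clusters and labelled
panels. Planted edits are applied before random mutation and are immune to
it, and indels are kept out of anchor windows (+/- 2 residues), so the
returned truth labels and position maps stay exact.

Structure side: ideal poly-Ala helices (1.5 A rise, 100 deg twist), random
coordinate clouds, and rigid-transformed noisy copies with the applied
transform recorded.

Everything is bit-reproducible given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import reference as ref
from .seqio import ClusterRecord, Gene, ProteinRecord
from .structmetrics import Structure

ASP_POSITIONS = ("I", "II", "none")


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth layout of one synthetic input."""

    seed: int = 0
    mutation_rate: float = 0.0
    indel_rate: float = 0.0
    qcn_motif: bool = True
    asp_position: str = "II"
    n_cationic: int = 3
    dap_code: bool = True
    sulfotransferase: bool = True
    annotate_sulfotransferase: bool = False
    n_decoys: int = 1
    forced_mutations: tuple[tuple[int, str], ...] = ()
    # structure generation
    helix_length: int = 18
    noise_sigma: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.mutation_rate <= 1.0 and 0.0 <= self.indel_rate <= 1.0):
            raise ValueError("rates must be in [0, 1]")
        if self.asp_position not in ASP_POSITIONS:
            raise ValueError(f"asp_position must be one of {ASP_POSITIONS}")
        if not (0 <= self.n_cationic <= 3):
            raise ValueError("n_cationic must be in 0..3")


def criteria_truth(spec: GeneratorSpec) -> dict[str, bool]:
    """The four criterion labels implied by a spec."""
    return {
        "triad_motif": spec.qcn_motif and spec.asp_position == "II",
        "cationic_site": spec.n_cationic >= 2,
        "dap_code": spec.dap_code,
        "sulfotransferase": spec.sulfotransferase,
    }


# ---------------------------------------------------------------------------
# sequence mutation machinery
# ---------------------------------------------------------------------------

def _mutate(seq: str, rng: np.random.Generator, mutation_rate: float,
            indel_rate: float, protected: set[int],
            offset: int = 1) -> tuple[str, dict[int, int | None]]:
    """Point-mutate and indel a sequence, tracking the true position map.

    ``protected`` holds 1-based positions (in ``offset`` numbering) immune to
    substitution; indels additionally avoid protected positions +/- 2.
    Returns the new sequence and a map from original residue number to the
    1-based position in the mutated sequence (None for deleted residues).
    """
    aa = ref.AA20
    indel_guard = set()
    for p in protected:
        indel_guard.update(range(p - 2, p + 3))
    out: list[str] = []
    mapping: dict[int, int | None] = {}
    for i, res in enumerate(seq):
        number = offset + i
        guarded = number in indel_guard
        if indel_rate and not guarded and rng.random() < indel_rate:
            if rng.random() < 0.5:
                mapping[number] = None          # deletion
                continue
            out.append(aa[rng.integers(20)])    # insertion before residue
        if number not in protected and mutation_rate and rng.random() < mutation_rate:
            choices = aa.replace(res, "")
            res = choices[rng.integers(len(choices))]
        out.append(res)
        mapping[number] = len(out)
    return "".join(out), mapping


def _random_protein(rng: np.random.Generator, length: int,
                    prefix: str = "decoy") -> str:
    aa = np.array(list(ref.AA20))
    return "".join(aa[rng.integers(20, size=length)])


# ---------------------------------------------------------------------------
# NRPS gene / TE variant
# ---------------------------------------------------------------------------

def _planted_sequence(spec: GeneratorSpec) -> tuple[list[str], set[int]]:
    """Apply planted edits to the full reference; return seq and protected set."""
    seq = list(ref.sulm_record().sequence)
    protected = set(ref.QCN_WINDOW) | set(ref.TRIAD) | set(ref.CATIONIC_POSITIONS)
    protected |= set(ref.code_positions()) | {ref.POSITION_I_SITE, ref.PCP_SER}

    if not spec.qcn_motif:
        seq[2819 - 1] = "V"   # hydrophobic residue replaces the motif Asn
    if spec.asp_position != "II":
        seq[ref.TRIAD[1] - 1] = "A"
    if spec.asp_position == "I":
        seq[ref.POSITION_I_SITE - 1] = "D"
    cationic_ablation = {0: "A", 1: "A", 2: "A"}
    for idx, pos in enumerate(ref.CATIONIC_POSITIONS):
        if idx >= spec.n_cationic:
            seq[pos - 1] = cationic_ablation[idx]
    if not spec.dap_code:
        for pos, res in zip(ref.code_positions(), ref.ALA_CODE):
            seq[pos - 1] = res

    for pos, res in spec.forced_mutations:
        if pos in protected:
            raise ValueError(
                f"forced mutation at {pos} contradicts a planted feature")
        seq[pos - 1] = res
    return seq, protected


def make_nrps_gene(spec: GeneratorSpec,
                   rng: np.random.Generator | None = None,
                   gene_id: str = "nrps1") -> tuple[ProteinRecord, dict]:
    """Full-length NRPS gene (C-A-PCP ... TE) with planted truth labels."""
    rng = rng or np.random.default_rng(spec.seed)
    seq, protected = _planted_sequence(spec)
    mutated, mapping = _mutate("".join(seq), rng, spec.mutation_rate,
                               spec.indel_rate, protected)
    record = ProteinRecord(id=gene_id, sequence=mutated,
                           description="synthetic NRPS gene")
    truth = {
        "spec": spec,
        "criteria": criteria_truth(spec),
        "position_map": mapping,
    }
    return record, truth


def make_te_variant(spec: GeneratorSpec,
                    rng: np.random.Generator | None = None,
                    linker: int = 0,
                    record_id: str = "te_variant") -> tuple[ProteinRecord, dict]:
    """TE-domain-sized variant, optionally embedded between random linkers.

    The truth position map keys are reference (SulM-frame) residue numbers;
    values are 1-based positions in the returned protein.
    """
    rng = rng or np.random.default_rng(spec.seed)
    seq, protected = _planted_sequence(spec)
    te_start, te_end = ref.TE_SPAN
    te_seq = "".join(seq[te_start - 1 : te_end])
    mutated, mapping = _mutate(te_seq, rng, spec.mutation_rate,
                               spec.indel_rate, protected, offset=te_start)
    left = _random_protein(rng, linker) if linker else ""
    right = _random_protein(rng, linker) if linker else ""
    full = left + mutated + right
    shift = len(left)
    mapping = {k: (v + shift if v is not None else None)
               for k, v in mapping.items()}
    record = ProteinRecord(id=record_id, sequence=full,
                           description="synthetic TE-domain variant")
    return record, {"spec": spec, "criteria": criteria_truth(spec),
                    "position_map": mapping}


def make_cluster(spec: GeneratorSpec,
                 cluster_id: str | None = None) -> tuple[ClusterRecord, dict]:
    """Synthetic gene cluster with a known four-criteria verdict."""
    rng = np.random.default_rng(spec.seed)
    genes: list[Gene] = []
    nrps, truth = make_nrps_gene(spec, rng)
    nrps_annot = "nonribosomal peptide synthetase"
    genes.append(Gene(gene_id=nrps.id,
                      protein=replace(nrps, description=nrps_annot),
                      annotation=nrps_annot, role="nrps"))
    if spec.sulfotransferase:
        suln_seq, _ = _mutate(ref.suln_record().sequence, rng,
                              spec.mutation_rate, spec.indel_rate, set())
        annotation = ("sulfotransferase" if spec.annotate_sulfotransferase
                      else "hypothetical protein")
        genes.append(Gene(
            gene_id="sulfo1",
            protein=ProteinRecord(id="sulfo1", sequence=suln_seq,
                                  description=annotation),
            annotation=annotation,
            role="sulfotransferase" if spec.annotate_sulfotransferase else "unknown",
        ))
    for i in range(spec.n_decoys):
        gid = f"decoy{i + 1}"
        genes.append(Gene(
            gene_id=gid,
            protein=ProteinRecord(id=gid, sequence=_random_protein(rng, 250),
                                  description="hypothetical protein"),
            annotation="hypothetical protein",
        ))
    cid = cluster_id or f"synthetic_cluster_{spec.seed}"
    cluster = ClusterRecord(cluster_id=cid, genes=tuple(genes))
    labels = criteria_truth(spec)
    n_passed = sum(labels.values())
    truth = {
        "spec": spec,
        "criteria": labels,
        "n_passed": n_passed,
        "call": "candidate" if n_passed == 4 else "rejected",
    }
    return cluster, truth


def make_panel(n_clusters: int, seed: int, mutation_rate: float = 0.0,
               indel_rate: float = 0.0) -> list[tuple[ClusterRecord, dict]]:
    """Panel of clusters with randomized planted feature combinations."""
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n_clusters):
        spec = GeneratorSpec(
            seed=int(rng.integers(2 ** 31)),
            mutation_rate=mutation_rate,
            indel_rate=indel_rate,
            qcn_motif=bool(rng.random() < 0.5),
            asp_position=("II", "I", "none")[int(rng.choice(3, p=(0.5, 0.25, 0.25)))],
            n_cationic=int(rng.integers(0, 4)),
            dap_code=bool(rng.random() < 0.5),
            sulfotransferase=bool(rng.random() < 0.5),
        )
        panel.append(make_cluster(spec, cluster_id=f"panel_{i:03d}"))
    return panel


# ---------------------------------------------------------------------------
# bundled demo sequences
# ---------------------------------------------------------------------------

def demo_te_records() -> tuple[list[ProteinRecord], set[str], set[str]]:
    """Demo TE-domain set: a position-II clade and a diverged position-I clade.

    Returns (records, position-II labels, position-I labels). Used by the
    documented walkthrough and the phylogeny demo: neighbor joining on
    1-identity distances should recover each group as monophyletic.
    """
    group2, group1 = set(), set()
    records: list[ProteinRecord] = []
    records.append(replace(ref.sulte_record(), id="SulTE_like_0"))
    group2.add("SulTE_like_0")
    for i, seed in enumerate((11, 12, 13), start=1):
        rec, _ = make_te_variant(
            GeneratorSpec(seed=seed, mutation_rate=0.08, asp_position="II"),
            record_id=f"SulTE_like_{i}")
        records.append(rec)
        group2.add(rec.id)
    base_spec = GeneratorSpec(seed=99, mutation_rate=0.35, asp_position="I")
    for i, seed in enumerate((21, 22, 23, 24), start=1):
        base_rng = np.random.default_rng(seed)
        base, _ = make_te_variant(base_spec, rng=np.random.default_rng(909),
                                  record_id=f"posI_{i}")
        extra, _ = _mutate(base.sequence, base_rng, 0.08, 0.0, set())
        rec = ProteinRecord(id=f"posI_{i}", sequence=extra,
                            description="synthetic position-I TE domain")
        records.append(rec)
        group1.add(rec.id)
    return records, group2, group1


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

def ideal_helix(n_res: int, rise: float = 1.5, twist_deg: float = 100.0,
                radius: float = 2.3) -> np.ndarray:
    """Calpha trace of an ideal alpha-helix along +z."""
    k = np.arange(n_res)
    theta = np.radians(twist_deg) * k
    return np.column_stack((radius * np.cos(theta),
                            radius * np.sin(theta),
                            rise * k))


def coords_to_structure(xyz: np.ndarray, chain: str = "A",
                        start_res: int = 1, resname: str = "ALA",
                        atname: str = "CA", element: str = "C") -> Structure:
    n = len(xyz)
    return Structure(
        chain=np.array([chain] * n, dtype=object),
        resseq=np.arange(start_res, start_res + n),
        icode=np.array([""] * n, dtype=object),
        resname=np.array([resname] * n, dtype=object),
        atname=np.array([atname] * n, dtype=object),
        element=np.array([element] * n, dtype=object),
        xyz=np.asarray(xyz, dtype=float),
        occupancy=np.ones(n),
        altloc=np.array([""] * n, dtype=object),
        het=np.zeros(n, dtype=bool),
    )


def merge_structures(*parts: Structure) -> Structure:
    fields = ("chain", "resseq", "icode", "resname", "atname", "element",
              "xyz", "occupancy", "altloc", "het")
    return Structure(*(np.concatenate([getattr(p, f) for p in parts])
                       for f in fields))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_cloud(rng: np.random.Generator, n: int = 30,
                 scale: float = 10.0) -> np.ndarray:
    return rng.normal(scale=scale, size=(n, 3))


def rigid_copy(xyz: np.ndarray, rng: np.random.Generator,
               noise_sigma: float = 0.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid-transformed (optionally noisy) copy; returns (copy, R, t)."""
    rot = random_rotation(rng)
    t = rng.normal(scale=20.0, size=3)
    out = xyz @ rot.T + t
    if noise_sigma > 0:
        out = out + rng.normal(scale=noise_sigma, size=out.shape)
    return out, rot, t


def make_toy_structure(spec: GeneratorSpec) -> tuple[Structure, dict]:
    """Helix (chain A) plus a rigid-transformed noisy copy (chain B).

    The truth dict records the applied rotation/translation and noise sigma.
    """
    rng = np.random.default_rng(spec.seed)
    helix = ideal_helix(spec.helix_length)
    copy, rot, t = rigid_copy(helix, rng, noise_sigma=spec.noise_sigma)
    structure = merge_structures(
        coords_to_structure(helix, chain="A"),
        coords_to_structure(copy, chain="B"),
    )
    return structure, {"rotation": rot, "translation": t,
                       "noise_sigma": spec.noise_sigma}
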