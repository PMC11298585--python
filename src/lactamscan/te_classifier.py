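"""Four-criteria screen for beta-lactam-forming NRPS thioesterase domains.

Candidate proteins are anchored to a reference thioesterase (TE) domain by
local alignment, and every criterion is evaluated in the reference residue
frame through a :class:`~lactamscan.pairwise_align.PositionMap`:

1. ``triad_motif`` — the catalytic triad carries the aspartate at
   "position II" (on the loop following strand beta7) and the
   Gln-Cys-Asn motif housing the nucleophilic cysteine.
2. ``cationic_site`` — at least two of the three basic active-site positions
   carry Arg or Lys, matching the positively charged sulfamate-binding pocket.
3. ``dap_code`` — the specificity code of the last-module adenylation domain
   best matches 2,3-diaminopropionate (DAP), the residue that closes the
   beta-lactam ring.
4. ``sulfotransferase`` — the cluster contains a sulfotransferase gene
   (by annotation keyword or by alignment to the reference sulfotransferase).

A cluster is called ``candidate`` when at least ``criteria_min`` (default:
all four) criteria pass.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from functools import lru_cache

from . import reference
from .pairwise_align import (
    UNALIGNED,
    AlignmentParams,
    AlignmentResult,
    PositionMap,
    align,
    full_position_map,
)
from .seqio import ClusterRecord, ProteinRecord

CRITERIA = ("triad_motif", "cationic_site", "dap_code", "sulfotransferase")


@dataclass(frozen=True)
class ReferenceAnchors:
    """Reference sequences plus the residue numbers every criterion reads."""

    te_sequence: str
    te_start: int
    triad: tuple[int, int, int]            # nucleophile, Asp, His
    qcn_window: tuple[int, int, int]
    cationic_positions: tuple[int, ...]
    lid_span: tuple[int, int]
    post_b7_span: tuple[int, int]
    position_i_window: tuple[int, int]
    a_sequence: str
    a_start: int
    code_positions: tuple[int, ...]
    sulfotransferase_sequence: str
    reference_id: str = "reference"

    def __post_init__(self):
        end = self.te_start + len(self.te_sequence) - 1
        for n in (*self.triad, *self.qcn_window, *self.cationic_positions,
                  *self.lid_span, *self.post_b7_span, *self.position_i_window):
            if not (self.te_start <= n <= end):
                raise ValueError(f"anchor {n} outside TE span {self.te_start}-{end}")
        if self.qcn_window[1] != self.triad[0]:
            raise ValueError("motif window must be centered on the nucleophile")
        a_end = self.a_start + len(self.a_sequence) - 1
        for n in self.code_positions:
            if not (self.a_start <= n <= a_end):
                raise ValueError(f"code position {n} outside A-domain span")


@lru_cache(maxsize=1)
def default_anchors() -> ReferenceAnchors:
    """Anchors built on the bundled synthetic SulM-like reference."""
    r = reference
    return ReferenceAnchors(
        te_sequence=r.sulte_record().sequence,
        te_start=r.TE_SPAN[0],
        triad=r.TRIAD,
        qcn_window=r.QCN_WINDOW,
        cationic_positions=r.CATIONIC_POSITIONS,
        lid_span=r.LID_SPAN,
        post_b7_span=r.POST_B7_SPAN,
        position_i_window=r.POSITION_I_WINDOW,
        a_sequence=r.a3_record().sequence,
        a_start=r.A3_SPAN[0],
        code_positions=r.code_positions(),
        sulfotransferase_sequence=r.suln_record().sequence,
        reference_id=r.sulm_record().id,
    )


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the screen. Score thresholds are raw BLOSUM62 units."""

    te_score_min: float = 100.0
    a_score_min: float = 150.0
    sulfo_score_min: float = 150.0
    dap_min_matches: int = 8
    dap_min_mapped: int = 6
    criteria_min: int = 4
    allow_ser_nucleophile: bool = False
    similarity_threshold: float = 0.70
    align_params: AlignmentParams = AlignmentParams(mode="local")
    min_segment: int = 30

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["align_params"] = dataclasses.asdict(self.align_params)
        return d


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    kind: str                       # "TE" or "A"
    query_span: tuple[int, int]
    alignment: AlignmentResult
    pmap: PositionMap
    protein: ProteinRecord

    def residue(self, ref_number: int) -> str | None:
        return self.pmap.residue(ref_number, self.protein.sequence)


@dataclass(frozen=True)
class TriadAssignment:
    nucleophile: tuple[int, str] | None
    asp: tuple[int, str] | None
    his: tuple[int, str] | None
    asp_position: str               # "I", "II" or "undetermined"
    note: str = ""


@dataclass(frozen=True)
class CriterionResult:
    criterion: str
    passed: bool
    evidence: str

    def __post_init__(self):
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.passed and not self.evidence:
            raise ValueError("passing criterion requires evidence")


@dataclass(frozen=True)
class SpecificityCode:
    code: str                       # 10 residues, "-" where unaligned
    gene_id: str
    module_index: int
    n_mapped: int

    @property
    def reliable(self) -> bool:
        return self.n_mapped >= 6


@dataclass(frozen=True)
class ClusterVerdict:
    cluster_id: str
    criteria: dict[str, CriterionResult]
    n_passed: int
    call: str                       # "candidate" or "rejected"
    te_gene_id: str | None
    a_gene_id: str | None
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "call": self.call,
            "n_passed": self.n_passed,
            "te_gene_id": self.te_gene_id,
            "a_gene_id": self.a_gene_id,
            "reason": self.reason,
            "criteria": {
                k: {"passed": v.passed, "evidence": v.evidence}
                for k, v in self.criteria.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterVerdict":
        return cls(
            cluster_id=d["cluster_id"],
            criteria={
                k: CriterionResult(criterion=k, passed=v["passed"],
                                   evidence=v["evidence"])
                for k, v in d["criteria"].items()
            },
            n_passed=d["n_passed"],
            call=d["call"],
            te_gene_id=d.get("te_gene_id"),
            a_gene_id=d.get("a_gene_id"),
            reason=d.get("reason", ""),
        )


# ---------------------------------------------------------------------------
# domain location
# ---------------------------------------------------------------------------

def _segment_hits(query: str, ref: str, params: AlignmentParams,
                  score_min: float, min_segment: int) -> list[tuple[AlignmentResult, int]]:
    """Greedy non-overlapping local hits: best hit first, then the flanks."""
    out: list[tuple[AlignmentResult, int]] = []

    def search(offset: int, segment: str) -> None:
        if len(segment) < min_segment:
            return
        aln = align(ref, segment, params)
        if aln.score < score_min or aln.query_span[1] < aln.query_span[0]:
            return
        out.append((aln, offset))
        qs, qe = aln.query_span
        search(offset, segment[: qs - 1])
        search(offset + qe, segment[qe:])

    search(0, query)
    out.sort(key=lambda t: (-t[0].score, t[1]))
    return out


def _domain_hits(protein: ProteinRecord, ref_seq: str, ref_start: int,
                 kind: str, score_min: float, config: ScreenConfig) -> list[DomainHit]:
    params = config.align_params
    if params.mode != "local":
        params = replace(params, mode="local")
    hits = []
    for aln, offset in _segment_hits(protein.sequence, ref_seq, params,
                                     score_min, config.min_segment):
        if offset:
            aln = replace(aln, query_span=(aln.query_span[0] + offset,
                                           aln.query_span[1] + offset))
        pmap = full_position_map(aln, ref_start=ref_start)
        hits.append(DomainHit(gene_id=protein.id, kind=kind,
                              query_span=aln.query_span, alignment=aln,
                              pmap=pmap, protein=protein))
    return hits


def find_te_domains(protein: ProteinRecord, anchors: ReferenceAnchors | None = None,
                    config: ScreenConfig | None = None) -> list[DomainHit]:
    """Locate thioesterase domains by local alignment to the reference TE.

    Returns non-overlapping hits above ``te_score_min``, best score first,
    each carrying a reference-frame position map for all anchors.
    """
    anchors = anchors or default_anchors()
    config = config or ScreenConfig()
    return _domain_hits(protein, anchors.te_sequence, anchors.te_start, "TE",
                        config.te_score_min, config)


def find_a_domains(protein: ProteinRecord, anchors: ReferenceAnchors | None = None,
                   config: ScreenConfig | None = None) -> list[DomainHit]:
    """Locate adenylation domains by local alignment to the reference A domain."""
    anchors = anchors or default_anchors()
    config = config or ScreenConfig()
    return _domain_hits(protein, anchors.a_sequence, anchors.a_start, "A",
                        config.a_score_min, config)


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

def _site(hit: DomainHit, ref_number: int) -> tuple[str | None, int | str]:
    q = hit.pmap.resolve(ref_number)
    if isinstance(q, int):
        return hit.protein.sequence[q - 1], q
    return None, q


def assign_triad(hit: DomainHit, anchors: ReferenceAnchors | None = None) -> TriadAssignment:
    """Read the catalytic triad off the position map and classify the Asp.

    Position II requires an Asp/Glu aligned to the reference position-II
    anchor (inside the post-beta7 loop); position I requires an acidic
    residue anchored in the window homologous to the loop after strand beta6.
    """
    if hit.kind != "TE":
        raise ValueError("triad assignment requires a TE hit")
    anchors = anchors or default_anchors()
    nuc_ref, asp_ref, his_ref = anchors.triad
    notes = []

    def read(ref_number):
        res, q = _site(hit, ref_number)
        if res is None:
            notes.append(f"anchor {ref_number} {q}")
            return None
        return (q, res)

    nuc, asp, his = read(nuc_ref), read(asp_ref), read(his_ref)

    if asp is not None and asp[1] in "DE":
        asp_position = "II"
    else:
        asp_position = "undetermined"
        lo, hi = anchors.position_i_window
        for ref_number in range(lo, hi + 1):
            res, q = _site(hit, ref_number)
            if res in ("D", "E"):
                asp_position = "I"
                asp = (q, res)
                notes.append(f"acidic residue anchored at position-I frame {ref_number}")
                break

    return TriadAssignment(nucleophile=nuc, asp=asp, his=his,
                           asp_position=asp_position, note="; ".join(notes))


def check_qcn_motif(hit: DomainHit, anchors: ReferenceAnchors | None = None,
                    config: ScreenConfig | None = None) -> CriterionResult:
    """Exact Gln-Cys-Asn check at the motif window around the nucleophile."""
    if hit.kind != "TE":
        raise ValueError("motif check requires a TE hit")
    anchors = anchors or default_anchors()
    config = config or ScreenConfig()
    expected = ("Q", "C", "N")
    found = []
    for ref_number, want in zip(anchors.qcn_window, expected):
        res, q = _site(hit, ref_number)
        if res is None:
            return CriterionResult("triad_motif", False,
                                   f"anchor {ref_number} unaligned")
        ok = res == want
        if want == "C" and config.allow_ser_nucleophile:
            ok = res in ("C", "S")
        found.append((ref_number, res, q, ok))
    passed = all(ok for *_, ok in found)
    evidence = ", ".join(f"{res}{q}({ref})" for ref, res, q, _ in found)
    return CriterionResult("triad_motif", passed, evidence)


def check_cationic_positions(hit: DomainHit,
                             anchors: ReferenceAnchors | None = None,
                             min_cationic: int = 2) -> CriterionResult:
    """Pass when >= 2 of the 3 basic active-site positions carry Arg or Lys."""
    if hit.kind != "TE":
        raise ValueError("cationic check requires a TE hit")
    anchors = anchors or default_anchors()
    parts, n_cat = [], 0
    for ref_number in anchors.cationic_positions:
        res, q = _site(hit, ref_number)
        if res is None:
            parts.append(f"-({ref_number})")
            continue
        if res in ("R", "K"):
            n_cat += 1
        parts.append(f"{res}{q}({ref_number})")
    evidence = f"{n_cat}/{len(anchors.cationic_positions)} cationic: " + ", ".join(parts)
    return CriterionResult("cationic_site", n_cat >= min_cationic, evidence)


def extract_a_code(protein: ProteinRecord,
                   anchors: ReferenceAnchors | None = None,
                   config: ScreenConfig | None = None,
                   te_hit: DomainHit | None = None) -> SpecificityCode:
    """Extract the 10-residue specificity code of the last-module A domain.

    "Last module" means the adenylation-domain hit closest upstream of the
    TE domain (or simply the most C-terminal hit when no TE hit is given).
    Raises ``ValueError("no A-domain")`` when nothing aligns above threshold.
    """
    anchors = anchors or default_anchors()
    config = config or ScreenConfig()
    hits = find_a_domains(protein, anchors, config)
    if te_hit is not None:
        hits = [h for h in hits if h.query_span[0] < te_hit.query_span[0]]
    if not hits:
        raise ValueError("no A-domain")
    by_pos = sorted(hits, key=lambda h: h.query_span[0])
    chosen = by_pos[-1]
    residues = []
    n_mapped = 0
    for ref_number in anchors.code_positions:
        res, _ = _site(chosen, ref_number)
        if res is None:
            residues.append("-")
        else:
            residues.append(res)
            n_mapped += 1
    return SpecificityCode(code="".join(residues), gene_id=protein.id,
                           module_index=by_pos.index(chosen) + 1,
                           n_mapped=n_mapped)


def match_dap_code(code: SpecificityCode, table: dict[str, str] | None = None,
                   config: ScreenConfig | None = None) -> CriterionResult:
    """Best-match the extracted code against the substrate code table.

    Match count ignores unaligned ("-") positions. Passes when DAP attains
    the maximal match count, with at least ``dap_min_matches`` matches, and
    the code is reliable (>= ``dap_min_mapped`` mapped positions).
    """
    table = table or reference.dap_code_table()
    config = config or ScreenConfig()
    if not table:
        raise ValueError("empty specificity-code table")
    scores = {
        name: sum(c == t for c, t in zip(code.code, entry) if c != "-")
        for name, entry in table.items()
    }
    best = max(scores.values())
    best_names = sorted(n for n, s in scores.items() if s == best)
    passed = (
        "DAP" in best_names
        and best >= config.dap_min_matches
        and code.n_mapped >= config.dap_min_mapped
    )
    evidence = (f"code {code.code} from {code.gene_id} module {code.module_index}; "
                f"best {'/'.join(best_names)} ({best}/10 matches)")
    if code.n_mapped < config.dap_min_mapped:
        evidence += f"; unreliable ({code.n_mapped} mapped)"
    return CriterionResult("dap_code", passed, evidence)


def find_sulfotransferase(cluster: ClusterRecord,
                          anchors: ReferenceAnchors | None = None,
                          config: ScreenConfig | None = None) -> CriterionResult:
    """Cluster-level sulfotransferase gene check (keyword or alignment)."""
    anchors = anchors or default_anchors()
    config = config or ScreenConfig()
    evidence = []
    for gene in cluster.genes:
        if gene.role == "sulfotransferase" or "sulfotransferase" in gene.annotation.lower():
            evidence.append(f"{gene.gene_id} (annotation)")
            continue
        if abs(len(gene.protein.sequence) - len(anchors.sulfotransferase_sequence)) > 2000:
            continue
        aln = align(anchors.sulfotransferase_sequence, gene.protein.sequence,
                    replace(config.align_params, mode="local"))
        if aln.score >= config.sulfo_score_min:
            evidence.append(f"{gene.gene_id} (alignment score {aln.score:.0f})")
    return CriterionResult("sulfotransferase", bool(evidence),
                           ", ".join(evidence) or "no sulfotransferase gene")


# ---------------------------------------------------------------------------
# cluster screen
# ---------------------------------------------------------------------------

def screen_cluster(cluster: ClusterRecord,
                   anchors: ReferenceAnchors | None = None,
                   config: ScreenConfig | None = None) -> ClusterVerdict:
    """Run the full four-criteria screen on one gene cluster."""
    anchors = anchors or default_anchors()
    config = config or ScreenConfig()

    te_hits = []
    for gene in cluster.genes:
        te_hits.extend(find_te_domains(gene.protein, anchors, config))
    crit: dict[str, CriterionResult] = {}
    crit["sulfotransferase"] = find_sulfotransferase(cluster, anchors, config)

    te_gene_id = a_gene_id = None
    reason = ""
    if not te_hits:
        reason = "no TE domain"
        for cid in ("triad_motif", "cationic_site", "dap_code"):
            crit[cid] = CriterionResult(cid, False, "no TE domain")
    else:
        te_hit = max(te_hits, key=lambda h: h.alignment.score)
        te_gene_id = te_hit.gene_id

        triad = assign_triad(te_hit, anchors)
        qcn = check_qcn_motif(te_hit, anchors, config)
        passed1 = qcn.passed and triad.asp_position == "II" and \
            triad.his is not None and triad.his[1] == "H"
        asp_txt = (f"Asp position {triad.asp_position}"
                   + (f" ({triad.asp[1]}{triad.asp[0]})" if triad.asp else ""))
        his_txt = f"His {triad.his[1]}{triad.his[0]}" if triad.his else "His unaligned"
        crit["triad_motif"] = CriterionResult(
            "triad_motif", passed1, f"{qcn.evidence}; {asp_txt}; {his_txt}")

        crit["cationic_site"] = check_cationic_positions(te_hit, anchors)

        te_gene = cluster.gene(te_gene_id)
        try:
            code = extract_a_code(te_gene.protein, anchors, config, te_hit=te_hit)
            crit["dap_code"] = match_dap_code(code, None, config)
            a_gene_id = code.gene_id
        except ValueError as exc:
            crit["dap_code"] = CriterionResult("dap_code", False, str(exc))

    n_passed = sum(c.passed for c in crit.values())
    call = "candidate" if (not reason and n_passed >= config.criteria_min) else "rejected"
    return ClusterVerdict(cluster_id=cluster.cluster_id, criteria=crit,
                          n_passed=n_passed, call=call,
                          te_gene_id=te_gene_id, a_gene_id=a_gene_id,
                          reason=reason)
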