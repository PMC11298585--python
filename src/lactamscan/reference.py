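"""Synthetic reference sequences for anchoring the screening criteria.

The screening pipeline is anchored to the sulfazecin NRPS SulM: a 2984-residue
protein whose module 3 ends in a peptidyl carrier protein (PCP, Ser2688
pantetheinylation site) followed by the beta-lactam-forming thioesterase
domain SulTE (residues 2723-2984), with the catalytic triad Cys2818 /
Asp2926 / His2956, the Gln2817-Cys2818-Asn2819 motif, the cationic
active-site positions Arg2849 / Lys2854 / Arg2858, the lid loop
Gly2844-Val2918 and the post-beta7 loop Gly2923-Val2946 that carries the
"position II" aspartate.

The sequences in this module are SYNTHETIC stand-ins: the deposited SulM
sequence is not bundled, so a deterministic pseudo-random protein is built
with every anchor residue planted at its published position and the anchor
windows kept free of confounding residues. All downstream logic reads anchor
numbers and sequences from configuration, so a real reference can be
substituted without code changes.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .seqio import ProteinRecord

_INTERNAL_SEED = 424243  # fixed: the reference is a constant, not a sample

AA20 = "ACDEFGHIKLMNPQRSTVWY"

FULL_LENGTH = 2984

# domain layout of the synthetic SulM-like protein (1-based, inclusive)
A2_SPAN = (480, 1010)       # module-2 adenylation domain
A3_SPAN = (2070, 2600)      # module-3 adenylation domain (the "last module")
PCP_SPAN = (2660, 2722)     # module-3 carrier protein
TE_SPAN = (2723, 2984)      # thioesterase domain (SulTE frame)

PCP_SER = 2688

TRIAD = (2818, 2926, 2956)           # nucleophile Cys, Asp, His
QCN_WINDOW = (2817, 2818, 2819)      # Gln-Cys-Asn motif
CATIONIC_POSITIONS = (2849, 2854, 2858)
LID_SPAN = (2844, 2918)
POST_B7_SPAN = (2923, 2946)
# loop position homologous to the canonical "position I" aspartate (after
# strand beta6, i.e. at the start of the lid region)
POSITION_I_WINDOW = (2845, 2851)
POSITION_I_SITE = 2847

# Stachelhaus/Challis specificity-code offsets in the GrsA frame, applied
# relative to the adenylation-domain start
CODE_OFFSETS = (235, 236, 239, 278, 299, 301, 322, 330, 331, 517)

DAP_CODE = "DVSEHTAVGK"   # synthetic: self-extracted from the reference A3
ALA_CODE = "DLFNNALTYK"

_PLANTED = {
    2817: "Q", 2818: "C", 2819: "N",     # Gln-Cys-Asn motif
    2844: "G", 2918: "V",                # lid-loop boundaries
    2849: "R", 2854: "K", 2858: "R",     # cationic active-site positions
    2856: "D",                           # gamma-glutamate contact
    2923: "G", 2946: "V",                # post-beta7 loop boundaries
    2926: "D",                           # position-II aspartate
    2932: "Y", 2933: "P",                # start of the alpha-3_10 helix
    2956: "H", 2957: "Y",                # catalytic His, pantetheine channel
    PCP_SER: "S",
    2733: "M", 2750: "A", 2756: "N",     # PCP-TE interface / oxyanion hole
}

SULN_LENGTH = 295


def code_positions(a_start: int = A3_SPAN[0]) -> tuple[int, ...]:
    """Absolute specificity-code positions for an A domain starting at a_start."""
    return tuple(a_start + off - 1 for off in CODE_OFFSETS)


def _scrub(seq: list[str], rng, span: tuple[int, int], forbidden: str,
           keep: set[int]) -> None:
    """Replace forbidden residues inside a window with neutral ones."""
    neutral = "STNQAG"
    for pos in range(span[0], span[1] + 1):
        if pos in keep:
            continue
        if seq[pos - 1] in forbidden:
            seq[pos - 1] = neutral[rng.integers(len(neutral))]


@lru_cache(maxsize=1)
def _build() -> tuple[str, str]:
    rng = np.random.default_rng(_INTERNAL_SEED)
    aa = np.array(list(AA20))
    seq = list(aa[rng.integers(20, size=FULL_LENGTH)])

    # module-2 A domain: diverged copy of module-3 A (same scaffold, ~20%
    # substitutions) carrying an alanine-like specificity code
    a3 = [seq[i - 1] for i in range(A3_SPAN[0], A3_SPAN[1] + 1)]
    a2 = list(a3)
    for i in range(len(a2)):
        if rng.random() < 0.20:
            a2[i] = aa[rng.integers(20)]
    for off, res in zip(CODE_OFFSETS, ALA_CODE):
        a2[off - 1] = res
    seq[A2_SPAN[0] - 1 : A2_SPAN[1]] = a2

    for off, res in zip(CODE_OFFSETS, DAP_CODE):
        seq[A3_SPAN[0] + off - 2] = res

    for pos, res in _PLANTED.items():
        seq[pos - 1] = res

    # keep the aspartate-position windows free of stray acidic residues so
    # the position I/II call is unambiguous on the reference
    _scrub(seq, rng, POST_B7_SPAN, "DE", keep={2926})
    _scrub(seq, rng, POSITION_I_WINDOW, "DE", keep=set())
    # and keep extra cationic residues out of the three-position window frame
    _scrub(seq, rng, (CATIONIC_POSITIONS[0] - 2, CATIONIC_POSITIONS[-1] + 2),
           "RK", keep=set(CATIONIC_POSITIONS))

    suln = "".join(aa[rng.integers(20, size=SULN_LENGTH)])
    return "".join(seq), suln


@lru_cache(maxsize=1)
def sulm_record() -> ProteinRecord:
    """Synthetic SulM-like NRPS (modules 2-3, C-A-PCP-E-C-A-PCP-TE layout)."""
    seq, _ = _build()
    return ProteinRecord(id="SulM_synthetic", sequence=seq,
                         description="SulM_synthetic sulfazecin NRPS (synthetic stand-in)")


def subsequence(record: ProteinRecord, span: tuple[int, int]) -> str:
    return record.sequence[span[0] - 1 : span[1]]


@lru_cache(maxsize=1)
def sulte_record() -> ProteinRecord:
    """Synthetic SulTE (thioesterase domain, SulM numbering 2723-2984)."""
    return ProteinRecord(
        id="SulTE_synthetic",
        sequence=subsequence(sulm_record(), TE_SPAN),
        description="SulTE_synthetic thioesterase domain (synthetic stand-in)",
    )


@lru_cache(maxsize=1)
def a3_record() -> ProteinRecord:
    """Synthetic module-3 (DAP-activating) adenylation domain."""
    return ProteinRecord(
        id="SulM_A3_synthetic",
        sequence=subsequence(sulm_record(), A3_SPAN),
        description="SulM_A3_synthetic adenylation domain (synthetic stand-in)",
    )


@lru_cache(maxsize=1)
def suln_record() -> ProteinRecord:
    """Synthetic SulN-like sulfotransferase."""
    _, suln = _build()
    return ProteinRecord(id="SulN_synthetic", sequence=suln,
                         description="SulN_synthetic sulfotransferase (synthetic stand-in)")


@lru_cache(maxsize=1)
def dap_code_table() -> dict[str, str]:
    """Specificity-code table (substrate -> 10-residue code), synthetic config.

    The DAP entry is self-extracted from the bundled reference A domain; the
    remaining entries are decoys differing from it at >= 3 positions.
    """
    rng = np.random.default_rng(_INTERNAL_SEED + 1)
    aa = AA20
    table = {"DAP": DAP_CODE, "Ala": ALA_CODE}
    for name in ("Ser", "Orn", "Thr"):
        while True:
            middle = "".join(aa[rng.integers(20)] for _ in range(8))
            code = "D" + middle + "K"
            diffs = sum(x != y for x, y in zip(code, DAP_CODE))
            if diffs >= 3 and code not in table.values():
                table[name] = code
                break
    return table
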