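"""Hairpin feature extraction: the 139-dimensional representation.

A pre-miRNA candidate is a short RNA that folds back on itself into a
stem-loop.  Real precursors differ from pseudo hairpins (hairpin-shaped
fragments of protein-coding sequence) in composition, secondary-structure
topology and folding energetics, and the classifier consumes all three
signal classes at once:

* 81 sequence features — 16 overlapping dinucleotide frequencies ``XY%``,
  the global ``G+C%`` content, and 64 overlapping trinucleotide
  frequencies ``XYZ%``;
* 49 structure features — 8 ensemble/topology scalars (``Diversity``,
  ``Freq``, ``dS``, ``dS/L``, ``dH``, ``dH/L``, ``dQ``, ``dF``), 9
  base-pair statistics (``|A-U|/L`` …, ``Avg_BP_Stem``, ``dD``, ``dP``)
  and 32 structure-triplet frequencies (8 pairedness patterns of a
  3-position window × the middle nucleotide);
* 9 energy features — ``dG``, the four normalized free-energy indices
  ``MFEI1``–``MFEI4``, ``NEFE``, ``Diff``, ``Tm`` and ``Tm/L``.

The exact formula behind every named feature is tabulated in
``docs/features.md``.  Feature extraction is a pure function: identical
input yields byte-identical output.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .errors import (
    FoldMismatchError,
    FoldingBackendError,
    IncompleteFoldError,
    InvalidAlphabetError,
    MalformedStructureError,
    TooShortError,
)

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"

#: 16 dinucleotide frequency names, fixed order.
DINUCLEOTIDE_NAMES: List[str] = [f"{x}{y}%" for x in RNA_ALPHABET for y in RNA_ALPHABET]
#: 64 trinucleotide frequency names, fixed order.
TRINUCLEOTIDE_NAMES: List[str] = [
    f"{x}{y}{z}%" for x in RNA_ALPHABET for y in RNA_ALPHABET for z in RNA_ALPHABET
]
SEQUENCE_FEATURE_NAMES: List[str] = DINUCLEOTIDE_NAMES + ["G+C%"] + TRINUCLEOTIDE_NAMES

TOPOLOGY_FEATURE_NAMES: List[str] = [
    "Diversity", "Freq", "dS", "dS/L", "dH", "dH/L", "dQ", "dF",
]
BASEPAIR_FEATURE_NAMES: List[str] = [
    "|A-U|/L", "|G-C|/L", "|G-U|/L",
    "|A-U|%/n_stems", "|G-C|%/n_stems", "|G-U|%/n_stems",
    "Avg_BP_Stem", "dD", "dP",
]
#: 8 pairedness patterns of a 3-window, ")" already remapped to "(".
TRIPLET_PATTERNS: List[str] = ["...", "..(", ".(.", ".((", "(..", "(.(", "((.", "((("]
TRIPLET_FEATURE_NAMES: List[str] = [
    f"{pat}_{mid}" for pat in TRIPLET_PATTERNS for mid in RNA_ALPHABET
]
STRUCTURE_FEATURE_NAMES: List[str] = (
    TOPOLOGY_FEATURE_NAMES + BASEPAIR_FEATURE_NAMES + TRIPLET_FEATURE_NAMES
)

ENERGY_FEATURE_NAMES: List[str] = [
    "dG", "MFEI1", "MFEI2", "MFEI3", "MFEI4", "NEFE", "Diff", "Tm", "Tm/L",
]

#: The frozen 139-name global ordering: sequence (81) + structure (49) + energy (9).
FEATURE_NAMES: List[str] = (
    SEQUENCE_FEATURE_NAMES + STRUCTURE_FEATURE_NAMES + ENERGY_FEATURE_NAMES
)

#: Named feature subsets selectable at the table/CLI level.
FEATURE_SUBSETS: Dict[str, List[str]] = {
    "all": FEATURE_NAMES,
    "sequence": SEQUENCE_FEATURE_NAMES,
    "structure": STRUCTURE_FEATURE_NAMES,
    "energy": ENERGY_FEATURE_NAMES,
}

FeatureVector = Dict[str, float]


def normalize_sequence(raw: str) -> str:
    """Uppercase, map T->U, and validate against the RNA alphabet."""
    seq = raw.strip().upper().replace("T", "U")
    bad = set(seq) - set(RNA_ALPHABET)
    if bad:
        raise InvalidAlphabetError(
            f"sequence contains non-RNA characters {sorted(bad)}"
        )
    if not seq:
        raise InvalidAlphabetError("sequence is empty")
    return seq


@dataclass(frozen=True)
class HairpinRecord:
    """A named RNA sequence; ``sequence`` is normalized on construction."""

    id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class HairpinFold:
    """Secondary structure plus thermodynamic scalars for one hairpin.

    ``structure`` is mandatory dot-bracket; every scalar is optional and
    only required by the features that consume it (missing ones raise
    :class:`IncompleteFoldError` at extraction time).  ``source`` records
    provenance: ``"viennarna"``, ``"file"`` or ``"synthetic"``.
    """

    structure: str
    dG: Optional[float] = None          # minimum free energy, kcal/mol
    EFE: Optional[float] = None         # ensemble free energy, kcal/mol
    Freq: Optional[float] = None        # frequency of the MFE structure, [0,1]
    Diversity: Optional[float] = None   # ensemble mean base-pair distance
    dS: Optional[float] = None          # structural entropy, cal/(mol K)
    dH: Optional[float] = None          # structural enthalpy, kcal/mol
    Tm: Optional[float] = None          # melting temperature, degrees C
    dQ: Optional[float] = None          # Shannon entropy of pairing probabilities
    dF: Optional[float] = None          # compactness of topology
    dP: Optional[float] = None          # base-pairing tendency
    dD: Optional[float] = None          # length-normalized base-pair distance
    source: str = "file"

    def __post_init__(self):
        validate_structure(self.structure)

    def require(self, *fields: str) -> None:
        for name in fields:
            if getattr(self, name) is None:
                raise IncompleteFoldError(name)


def validate_structure(structure: str) -> None:
    """Check a dot-bracket string: legal characters and balanced brackets."""
    if not structure:
        raise MalformedStructureError("empty structure")
    bad = set(structure) - set("(.)")
    if bad:
        raise MalformedStructureError(f"illegal structure characters {sorted(bad)}")
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise MalformedStructureError("unbalanced brackets: ')' before '('")
    if depth != 0:
        raise MalformedStructureError("unbalanced brackets: unclosed '('")


def base_pairs(structure: str) -> List[Tuple[int, int]]:
    """0-based (i, j) pairs from a dot-bracket string, sorted by i."""
    validate_structure(structure)
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    return sorted(pairs)


def stems(structure: str) -> List[List[Tuple[int, int]]]:
    """Maximal runs of >= 3 contiguously stacked base pairs.

    Two pairs stack when (i, j) is followed by (i+1, j-1).  Shorter runs
    are not counted as stems.
    """
    pairs = base_pairs(structure)
    runs: List[List[Tuple[int, int]]] = []
    current: List[Tuple[int, int]] = []
    for p in pairs:
        if current and p == (current[-1][0] + 1, current[-1][1] - 1):
            current.append(p)
        else:
            if current:
                runs.append(current)
            current = [p]
    if current:
        runs.append(current)
    return [r for r in runs if len(r) >= 3]


def n_stems(structure: str) -> int:
    return len(stems(structure))


def n_loops(structure: str) -> int:
    """Number of hairpin loops: innermost pairs enclosing only unpaired bases."""
    return len(re.findall(r"\(\.*\)", structure))


def _check_consistent(rec: HairpinRecord, fold: HairpinFold) -> None:
    if len(fold.structure) != rec.length:
        raise FoldMismatchError(
            f"structure length {len(fold.structure)} != sequence length "
            f"{rec.length} for record {rec.id!r}"
        )


# ---------------------------------------------------------------------------
# sequence features (81)
# ---------------------------------------------------------------------------

def extract_sequence_features(rec: HairpinRecord) -> FeatureVector:
    """16 XY% + G+C% + 64 XYZ% from overlapping k-mer windows.

    Dinucleotide counts are taken over the L-1 overlapping windows and
    trinucleotides over the L-2 windows, so each group is a probability
    distribution over its k-mers.
    """
    seq = rec.sequence
    L = rec.length
    if L < 3:
        raise TooShortError(f"sequence of length {L} < 3 for record {rec.id!r}")
    out: FeatureVector = {}
    for name in DINUCLEOTIDE_NAMES:
        out[name] = 0.0
    for i in range(L - 1):
        out[f"{seq[i:i + 2]}%"] += 1.0
    for name in DINUCLEOTIDE_NAMES:
        out[name] /= L - 1
    out["G+C%"] = sum(1 for c in seq if c in "GC") / L
    tri: FeatureVector = {name: 0.0 for name in TRINUCLEOTIDE_NAMES}
    for i in range(L - 2):
        tri[f"{seq[i:i + 3]}%"] += 1.0
    for name in TRINUCLEOTIDE_NAMES:
        out[name] = tri[name] / (L - 2)
    return out


# ---------------------------------------------------------------------------
# structure features (49)
# ---------------------------------------------------------------------------

def _pair_kind(a: str, b: str) -> Optional[str]:
    """Canonical pair class of two nucleotides: AU, GC, GU, or None."""
    duo = frozenset((a, b))
    if duo == frozenset("AU"):
        return "AU"
    if duo == frozenset("GC"):
        return "GC"
    if duo == frozenset("GU"):
        return "GU"
    return None


def extract_structure_features(rec: HairpinRecord, fold: HairpinFold) -> FeatureVector:
    """8 topology + 9 base-pair + 32 structure-triplet features.

    Topology scalars come straight off the fold.  Base-pair counts are
    orientation-insensitive (an A·U pair counts as |A-U| regardless of
    which arm carries the A).  The ``|X-Y|%/n_stems`` features divide the
    stem-region fraction of each pair class by the stem count; they and
    ``Avg_BP_Stem`` are defined as 0 when the structure has no stem, and
    pair-class fractions as 0 when there are no pairs at all.
    """
    _check_consistent(rec, fold)
    fold.require("Diversity", "Freq", "dS", "dH", "dQ", "dF", "dP", "dD")
    seq, struct, L = rec.sequence, fold.structure, rec.length

    out: FeatureVector = {
        "Diversity": fold.Diversity,
        "Freq": fold.Freq,
        "dS": fold.dS,
        "dS/L": fold.dS / L,
        "dH": fold.dH,
        "dH/L": fold.dH / L,
        "dQ": fold.dQ,
        "dF": fold.dF,
    }

    pairs = base_pairs(struct)
    stem_runs = stems(struct)
    stem_pairs = {p for run in stem_runs for p in run}
    counts = {"AU": 0, "GC": 0, "GU": 0}
    stem_counts = {"AU": 0, "GC": 0, "GU": 0}
    for (i, j) in pairs:
        kind = _pair_kind(seq[i], seq[j])
        if kind is None:
            continue  # non-canonical pair in a supplied structure: ignored
        counts[kind] += 1
        if (i, j) in stem_pairs:
            stem_counts[kind] += 1
    total = len(pairs)
    ns = len(stem_runs)
    for kind, label in (("AU", "A-U"), ("GC", "G-C"), ("GU", "G-U")):
        out[f"|{label}|/L"] = counts[kind] / L
        if total > 0 and ns > 0:
            out[f"|{label}|%/n_stems"] = (stem_counts[kind] / total) / ns
        else:
            out[f"|{label}|%/n_stems"] = 0.0
    out["Avg_BP_Stem"] = total / ns if ns > 0 else 0.0
    out["dD"] = fold.dD
    out["dP"] = fold.dP
    if ns == 0 and total > 0:
        logger.warning(
            "record %s: %d base pairs but no stem of >=3 stacked pairs; "
            "stem-denominated features set to 0", rec.id, total
        )

    if L < 3:
        raise TooShortError(f"structure of length {L} < 3 for record {rec.id!r}")
    paired = struct.replace(")", "(")
    tri: FeatureVector = {name: 0.0 for name in TRIPLET_FEATURE_NAMES}
    for i in range(L - 2):
        tri[f"{paired[i:i + 3]}_{seq[i + 1]}"] += 1.0
    for name in TRIPLET_FEATURE_NAMES:
        out[name] = tri[name] / (L - 2)
    return out


# ---------------------------------------------------------------------------
# energy features (9)
# ---------------------------------------------------------------------------

def extract_energy_features(rec: HairpinRecord, fold: HairpinFold) -> FeatureVector:
    """dG, MFEI1-4, NEFE, Diff, Tm, Tm/L.

    Conventions: MFEI1 = (dG/L) / GC-fraction (0 when GC = 0);
    MFEI2 = (dG/L)/n_stems and MFEI3 = (dG/L)/n_loops (0 when the
    denominator count is 0); MFEI4 = dG / number of base pairs (0 for an
    unpaired structure); NEFE = EFE/L; Diff = |dG - EFE| / L.
    """
    _check_consistent(rec, fold)
    fold.require("dG", "EFE", "Tm")
    L = rec.length
    dg_per_nt = fold.dG / L
    gc = sum(1 for c in rec.sequence if c in "GC") / L
    ns = n_stems(fold.structure)
    nl = n_loops(fold.structure)
    nbp = len(base_pairs(fold.structure))
    if gc == 0.0 or ns == 0 or nl == 0 or nbp == 0:
        logger.warning(
            "record %s: zero denominator (GC=%.2f, n_stems=%d, n_loops=%d, "
            "n_bp=%d); affected MFEI features set to 0", rec.id, gc, ns, nl, nbp
        )
    return {
        "dG": fold.dG,
        "MFEI1": dg_per_nt / gc if gc > 0 else 0.0,
        "MFEI2": dg_per_nt / ns if ns > 0 else 0.0,
        "MFEI3": dg_per_nt / nl if nl > 0 else 0.0,
        "MFEI4": fold.dG / nbp if nbp > 0 else 0.0,
        "NEFE": fold.EFE / L,
        "Diff": abs(fold.dG - fold.EFE) / L,
        "Tm": fold.Tm,
        "Tm/L": fold.Tm / L,
    }


def extract_features(rec: HairpinRecord, fold: HairpinFold) -> FeatureVector:
    """The full 139-feature vector: sequence + structure + energy groups."""
    merged: FeatureVector = {}
    merged.update(extract_sequence_features(rec))
    merged.update(extract_structure_features(rec, fold))
    merged.update(extract_energy_features(rec, fold))
    return {name: merged[name] for name in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# folding backend
# ---------------------------------------------------------------------------

# Nearest-neighbor stack enthalpies, kcal/mol, indexed by the two stacked
# pairs read 5'->3' on the outer strand.  Watson-Crick values follow the
# Turner-style RNA parameter sets; wobble-containing stacks use a pooled
# value.  These feed the dH/dS/Tm surrogates only.
_STACK_DH = {
    ("AU", "AU"): -6.82, ("AU", "UA"): -9.38, ("UA", "AU"): -7.69,
    ("UA", "UA"): -6.82, ("AU", "GC"): -10.48, ("AU", "CG"): -11.40,
    ("UA", "GC"): -10.44, ("UA", "CG"): -12.44, ("GC", "AU"): -12.44,
    ("GC", "UA"): -11.40, ("CG", "AU"): -10.44, ("CG", "UA"): -10.48,
    ("GC", "GC"): -13.39, ("GC", "CG"): -14.88, ("CG", "GC"): -10.64,
    ("CG", "CG"): -13.39,
}
_WOBBLE_DH = -8.0
_T37 = 310.15  # K
_KT37 = 0.0019872 * _T37  # kcal/mol


def _oriented_pair(seq: str, i: int, j: int) -> str:
    return seq[i] + seq[j]


def _stack_enthalpy(seq: str, structure: str) -> float:
    """Sum of nearest-neighbor enthalpies over stacked pairs of the MFE fold."""
    pairs = base_pairs(structure)
    pair_set = set(pairs)
    dh = 0.0
    for (i, j) in pairs:
        if (i + 1, j - 1) in pair_set:
            key = (_oriented_pair(seq, i, j), _oriented_pair(seq, i + 1, j - 1))
            dh += _STACK_DH.get(key, _WOBBLE_DH)
    return dh


def fold_hairpin(rec: HairpinRecord) -> HairpinFold:
    """Fold one hairpin with the ViennaRNA library and fill every scalar.

    MFE structure, ensemble free energy, MFE-structure frequency, ensemble
    diversity and the pairing-probability entropies come from RNAlib's MFE
    and partition-function folds at 37 C.  Melting thermodynamics are not
    part of equilibrium folding, so dH is accumulated from nearest-neighbor
    stack enthalpies over the MFE structure, dS = (dH - dG)/T and
    Tm = dH/dS (converted to Celsius); the fold's ``source`` field records
    that these came from this backend.
    """
    try:
        import RNA  # ViennaRNA python bindings
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise FoldingBackendError(
            "ViennaRNA python bindings are not importable; fold externally "
            "and supply precomputed fold files instead"
        ) from exc

    seq = rec.sequence
    fc = RNA.fold_compound(seq)
    structure, mfe = fc.mfe()
    fc.exp_params_rescale(mfe)
    _, efe = fc.pf()
    freq = min(1.0, math.exp((efe - mfe) / _KT37))
    diversity = fc.mean_bp_distance()
    L = rec.length

    # positional Shannon entropy of pairing probabilities (bits)
    bpp = fc.bpp()  # 1-based (L+1) x (L+1), upper triangle
    paired_p = [0.0] * L
    ent = [0.0] * L
    for i in range(1, L + 1):
        for j in range(i + 1, L + 1):
            p = bpp[i][j]
            if p > 0.0:
                paired_p[i - 1] += p
                paired_p[j - 1] += p
                h = -p * math.log2(p)
                ent[i - 1] += h
                ent[j - 1] += h
    for i in range(L):
        q = max(0.0, 1.0 - paired_p[i])
        if q > 0.0:
            ent[i] += -q * math.log2(q)
    dq = sum(ent) / L
    # compactness: 1 for a perfectly defined ensemble, ->0 as pairing smears
    df = 1.0 - dq / math.log2(L) if L > 1 else 1.0

    nbp = len(base_pairs(structure))
    dh = _stack_enthalpy(seq, structure)
    ds = (dh - mfe) * 1000.0 / _T37  # cal/(mol K)
    tm = (dh * 1000.0 / ds - 273.15) if abs(ds) > 1e-9 else 0.0

    return HairpinFold(
        structure=structure,
        dG=round(mfe, 2),
        EFE=round(efe, 2),
        Freq=freq,
        Diversity=diversity,
        dS=ds,
        dH=dh,
        Tm=tm,
        dQ=dq,
        dF=df,
        dP=nbp / L,
        dD=diversity / L,
        source="viennarna",
    )
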