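"""File formats: FASTA, Vienna-style fold files, TSV tables, run configs.

The interchange format between featurization and learning is a TSV
feature table (first column ``id``, then named feature columns, optional
``label`` column with 1 = real pre-miRNA), so the classifier runs on any
labeled numeric table — including the synthetic benchmark.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DuplicateIdError, ParseError
from .features import FEATURE_NAMES, FeatureVector, HairpinFold, HairpinRecord

#: Sidecar TSV columns carrying thermodynamic scalars per record id.
SIDECAR_FIELDS = ["dG", "EFE", "Freq", "Diversity", "dS", "dH", "Tm",
                  "dQ", "dF", "dP", "dD"]


def read_fasta(path) -> List[HairpinRecord]:
    """Parse a multi-record FASTA with line-numbered diagnostics.

    Ids are the first whitespace-delimited token of the header;
    T is mapped to U and case is folded by HairpinRecord itself.
    """
    records: List[HairpinRecord] = []
    seen: Dict[str, int] = {}
    header: Optional[str] = None
    header_line = 0
    chunks: List[str] = []

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise ParseError(f"record {header!r} has no sequence", header_line)
        try:
            records.append(HairpinRecord(id=header, sequence="".join(chunks)))
        except Exception as exc:
            raise ParseError(f"record {header!r}: {exc}", header_line) from exc

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError("empty FASTA header", lineno)
                if header in seen:
                    raise DuplicateIdError(
                        f"duplicate id {header!r} (first seen at line "
                        f"{seen[header]})", lineno)
                seen[header] = lineno
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError("sequence data before any header", lineno)
                chunks.append(line)
    flush()
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return records


def write_fasta(records: List[HairpinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


_ENERGY_RE = re.compile(r"^(?P<struct>[(.)]+)\s*\(\s*(?P<dg>-?\d+(?:\.\d+)?)\s*\)$")


def read_fold_file(path, sidecar=None) -> Dict[str, HairpinFold]:
    """Parse a Vienna-style fold file, optionally merging a sidecar TSV.

    Record layout: ``>id`` line, sequence line, then the dot-bracket line
    with a trailing parenthesized MFE, e.g. ``((((....)))) (-5.40)``.
    The sidecar supplies the remaining thermodynamic scalars per id.
    """
    folds: Dict[str, HairpinFold] = {}
    lengths: Dict[str, int] = {}
    with open(path) as fh:
        lines = [(n, l.strip()) for n, l in enumerate(fh, start=1) if l.strip()]
    i = 0
    while i < len(lines):
        lineno, line = lines[i]
        if not line.startswith(">"):
            raise ParseError(f"expected '>' header, got {line!r}", lineno)
        rid = line[1:].split()[0]
        if rid in folds:
            raise DuplicateIdError(f"duplicate id {rid!r} in fold file", lineno)
        if i + 2 >= len(lines):
            raise ParseError(f"truncated record {rid!r}", lineno)
        seq_no, seq = lines[i + 1]
        st_no, st_line = lines[i + 2]
        m = _ENERGY_RE.match(st_line)
        if m:
            structure, dg = m.group("struct"), float(m.group("dg"))
        elif set(st_line) <= set("(.)"):
            structure, dg = st_line, None
        else:
            raise ParseError(
                f"malformed structure line {st_line!r} for {rid!r}", st_no)
        if len(structure) != len(seq):
            raise ParseError(
                f"structure length {len(structure)} != sequence length "
                f"{len(seq)} for {rid!r}", st_no)
        try:
            folds[rid] = HairpinFold(structure=structure, dG=dg, source="file")
        except Exception as exc:
            raise ParseError(f"record {rid!r}: {exc}", st_no) from exc
        lengths[rid] = len(seq)
        i += 3
    if sidecar is not None:
        merge_fold_sidecar(folds, sidecar)
    return folds


def merge_fold_sidecar(folds: Dict[str, HairpinFold], sidecar) -> None:
    """Fill thermodynamic scalars from a TSV with an ``id`` column."""
    df = pd.read_csv(sidecar, sep="\t")
    if "id" not in df.columns:
        raise ParseError(f"sidecar {sidecar} lacks an 'id' column")
    for _, row in df.iterrows():
        fold = folds.get(str(row["id"]))
        if fold is None:
            continue
        for name in SIDECAR_FIELDS:
            if name in df.columns and pd.notna(row[name]):
                setattr(fold, name, float(row[name]))


def write_fold_file(
    records: List[HairpinRecord], folds: Dict[str, HairpinFold], path
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fold = folds[rec.id]
            dg = fold.dG if fold.dG is not None else 0.0
            fh.write(f">{rec.id}\n{rec.sequence}\n{fold.structure} ({dg:.2f})\n")


def write_fold_sidecar(folds: Dict[str, HairpinFold], path) -> None:
    rows = []
    for rid, fold in folds.items():
        row = {"id": rid}
        for name in SIDECAR_FIELDS:
            row[name] = getattr(fold, name)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature / prediction tables
# ---------------------------------------------------------------------------

def features_to_frame(
    ids: List[str], vectors: List[FeatureVector]
) -> pd.DataFrame:
    df = pd.DataFrame(vectors, columns=FEATURE_NAMES)
    df.insert(0, "id", ids)
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(
    path,
) -> Tuple[List[str], np.ndarray, Optional[np.ndarray], List[str]]:
    """Read a TSV feature table -> (ids, X, labels-or-None, feature names)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2 or df.columns[0] != "id":
        raise ParseError(f"{path}: first column must be 'id'")
    ids = df["id"].astype(str).tolist()
    labels = None
    if "label" in df.columns:
        labels = df["label"].to_numpy()
        df = df.drop(columns=["label"])
    names = [c for c in df.columns if c != "id"]
    X = df[names].to_numpy(dtype=float)
    return ids, X, labels, names


# ---------------------------------------------------------------------------
# flat run-config files
# ---------------------------------------------------------------------------

#: Keys accepted in a flat ``key = value`` config file (CLI option names).
CONFIG_KEYS = {
    "cp", "cn", "iterations", "seed", "svm_c", "svm_gamma",
    "feature_subset", "verbose",
}


def read_config(path) -> Dict[str, str]:
    """Parse a flat ``key = value`` config file; unknown keys are rejected."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"expected 'key = value', got {line!r}", lineno)
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in CONFIG_KEYS:
                raise ParseError(f"unknown config key {key!r}", lineno)
            out[key] = value
    return out
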