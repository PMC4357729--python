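"""Data model and file I/O for spectral-count tables, GO annotations and PPI edges.

Spectral counts live in a long (tidy) TSV with columns
``protein_id, sample, fraction, count``.  A triple that does not appear in
the file is a protein that was not identified in that sample/fraction and
is read as count 0.  Canonical sample labels for the bait pull-down design
are ``control`` (negative-control purification), ``proliferating``
(maintenance-condition NSCs) and ``differentiating`` (NSCs after induction
of neuronal differentiation), each NSC sample usually split into
cytoplasmic and nuclear fractions that are summed before quantification.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

CANONICAL_SAMPLES = ("control", "proliferating", "differentiating")
MERGED_FRACTION = "whole"

COUNT_COLUMNS = ("protein_id", "sample", "fraction", "count")


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class StateError(RuntimeError):
    """An operation was applied to an object in the wrong state."""


@dataclass
class CountMatrix:
    """Protein x sample (x fraction) nonnegative integer spectral counts.

    ``data`` is a long-format frame with columns protein_id, sample,
    fraction, count.  Absent (protein, sample, fraction) triples mean
    count 0.  ``merged`` records whether fractions have been summed into
    the single reserved fraction ``"whole"``.
    """

    data: pd.DataFrame
    merged: bool = False

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"count table missing column(s): {', '.join(missing)}")
        self.data = df.loc[:, list(COUNT_COLUMNS)].reset_index(drop=True)
        counts = self.data["count"]
        if len(counts) and ((counts < 0).any() or counts.dtype.kind not in "iu"):
            raise ValueError("spectral counts must be nonnegative integers")
        dup = self.data.duplicated(subset=["protein_id", "sample", "fraction"])
        if dup.any():
            row = self.data.loc[dup.idxmax()]
            raise FormatError(
                "duplicate (protein, sample, fraction) triple: "
                f"({row.protein_id}, {row.sample}, {row.fraction})"
            )

    @property
    def proteins(self) -> list[str]:
        """Protein identifiers in first-appearance order."""
        return list(pd.unique(self.data["protein_id"]))

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))

    def counts(self, sample: str) -> pd.Series:
        """Merged counts for one sample indexed by protein, zeros included.

        Requires ``merged``; every protein in the matrix gets a value.
        """
        if not self.merged:
            raise StateError("counts() requires a fraction-merged matrix")
        sub = self.data[self.data["sample"] == sample]
        ser = sub.set_index("protein_id")["count"]
        return ser.reindex(self.proteins, fill_value=0).astype(int)

    def __eq__(self, other: object) -> bool:  # counts-equality, zero-padded
        if not isinstance(other, CountMatrix):
            return NotImplemented
        a = self.data.sort_values(list(COUNT_COLUMNS)).reset_index(drop=True)
        b = other.data.sort_values(list(COUNT_COLUMNS)).reset_index(drop=True)
        return self.merged == other.merged and a.equals(b)


@dataclass(frozen=True)
class SampleSummary:
    """Identified-protein counts per sample, their union and pairwise overlaps."""

    per_sample: dict[str, int]
    union: int
    intersections: dict[tuple[str, str], int]


@dataclass
class AnnotationMap:
    """Protein -> set of GO term ids, with an optional term-name lookup."""

    protein_to_terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for t in self.protein_to_terms.values():
            out |= t
        return out

    def annotated(self, term: str, universe: Iterable[str]) -> set[str]:
        return {p for p in universe if term in self.protein_to_terms.get(p, ())}


@dataclass
class EdgeList:
    """Typed undirected PPI edges, canonicalized by sorted endpoint pair.

    An edge is the triple (source, interaction type, target); the unordered
    endpoint pair plus the type is unique.
    """

    edges: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        canon: list[tuple[str, str, str]] = []
        for s, t, g in self.edges:
            a, b = sorted((s, g))
            key = (a, t, b)
            if key not in seen:
                seen.add(key)
                canon.append(key)
        self.edges = canon

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, _, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.edges)


def read_count_table(path: str | Path | io.TextIOBase) -> CountMatrix:
    """Read a long-format TSV spectral-count table.

    The header must contain protein_id, sample, fraction, count; counts
    must parse as nonnegative integers.  Duplicate triples are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"count table missing column(s): {', '.join(missing)}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts != counts.round()) | (counts < 0)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(f"line {line}: count {df['count'][bad.idxmax()]!r} "
                         "is not a nonnegative integer")
    df = df.assign(count=counts.astype(int))
    return CountMatrix(df, merged=False)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    cm.data.to_csv(path, sep="\t", index=False)


def sum_fractions(cm: CountMatrix) -> CountMatrix:
    """Sum cytoplasmic/nuclear (or any) fractions into one "whole" fraction.

    Fraction summation precedes all quantification; per (protein, sample)
    the merged count is the plain sum of all fraction counts.
    """
    if cm.merged:
        raise StateError("fractions already merged")
    agg = (
        cm.data.groupby(["protein_id", "sample"], sort=False, as_index=False)["count"]
        .sum()
    )
    agg.insert(2, "fraction", MERGED_FRACTION)
    return CountMatrix(agg, merged=True)


def sample_summary(cm: CountMatrix) -> SampleSummary:
    """Identified-protein counts (count > 0) per sample, union and overlaps."""
    if not cm.merged:
        raise StateError("sample_summary requires a fraction-merged matrix")
    present: dict[str, set[str]] = {}
    for s in cm.samples:
        ser = cm.counts(s)
        present[s] = set(ser.index[ser > 0])
    union: set[str] = set().union(*present.values()) if present else set()
    samples = list(present)
    inter = {
        (a, b): len(present[a] & present[b])
        for i, a in enumerate(samples)
        for b in samples[i + 1:]
    }
    return SampleSummary(
        per_sample={s: len(p) for s, p in present.items()},
        union=len(union),
        intersections=inter,
    )


def read_annotations(path: str | Path, names_path: str | Path | None = None) -> AnnotationMap:
    """Read a protein -> GO-term TSV (columns protein_id, go_id).

    ``names_path`` optionally maps go_id to a human-readable name
    (columns go_id, name).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "go_id"):
        if col not in df.columns:
            raise FormatError(f"annotation table missing column: {col}")
    mapping: dict[str, set[str]] = {}
    for prot, term in zip(df["protein_id"], df["go_id"]):
        mapping.setdefault(prot, set()).add(term)
    names: dict[str, str] = {}
    if names_path is not None:
        nd = pd.read_csv(names_path, sep="\t", dtype=str)
        for col in ("go_id", "name"):
            if col not in nd.columns:
                raise FormatError(f"term-name table missing column: {col}")
        names = dict(zip(nd["go_id"], nd["name"]))
    return AnnotationMap(mapping, names)


def write_annotations(am: AnnotationMap, path: str | Path) -> None:
    rows = [
        {"protein_id": p, "go_id": t}
        for p in sorted(am.protein_to_terms)
        for t in sorted(am.protein_to_terms[p])
    ]
    pd.DataFrame(rows, columns=["protein_id", "go_id"]).to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> EdgeList:
    """Read a SIF edge list: three fields per row.

    Tab-delimited rows may carry interaction types containing spaces
    (e.g. "transcription regulation"); rows without tabs are split on
    any whitespace.
    """
    edges: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise FormatError(f"line {i}: expected 3 SIF fields, got {len(fields)}")
            src, kind, tgt = fields
            edges.append((src, kind, tgt))
    return EdgeList(edges)


def write_edges(el: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, t, b in el.edges:
            fh.write(f"{a}\t{t}\t{b}\n")


def write_results(
    tables: Mapping[str, pd.DataFrame],
    directory: str | Path,
    config_echo: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write one TSV per stage plus a plain-text run manifest.

    The manifest records the package version, the configuration echo and
    per-stage row counts — enough to rerun the pipeline exactly.  Nothing
    time-dependent is written, so identical inputs give identical bytes.
    """
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = directory / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    manifest = directory / "manifest.txt"
    with open(manifest, "w") as fh:
        fh.write(f"nsc-interactome version: {__version__}\n")
        fh.write("[row counts]\n")
        for name, df in tables.items():
            fh.write(f"{name}: {len(df)}\n")
        fh.write("[config]\n")
        for key, val in sorted((config_echo or {}).items()):
            fh.write(f"{key}: {val}\n")
    paths["manifest"] = manifest
    return paths
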