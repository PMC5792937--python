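"""Alignment character accounting and simple binary indel coding.

Per-site classification follows the parsimony convention: counting
only unambiguous nucleotides (A, C, G, T; gaps, '?' and IUPAC ambiguity
codes are treated as missing), a site is constant when at most one
state is present, parsimony-informative when at least two states each
occur in at least two taxa, and variable-but-uninformative otherwise.

Indels are coded by the simple indel coding principle: every distinct
internal gap — a maximal run of '-' with identical start and end
columns across the taxa sharing it — becomes one binary
presence/absence character.  A taxon scores 1 when it carries exactly
that gap, 0 when it has contiguous determined sequence across the span,
and '?' when a different, overlapping gap (or missing data in the span)
makes the homology ambiguous.  Leading and trailing terminal gaps are
treated as missing data, not indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .errors import DataError

UNAMBIGUOUS = frozenset("ACGT")
MISSING = frozenset("?NX.")


@dataclass
class Alignment:
    """Equal-length character rows over nucleotides, gaps and ambiguity
    codes, with unique taxon labels."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise DataError("empty alignment")
        if len(set(self.taxa)) != len(self.taxa):
            raise DataError("duplicate taxon labels in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise DataError("alignment rows have unequal lengths")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = sorted(set(taxa) - set(index))
        if missing:
            raise DataError(f"taxa not in alignment: {missing}")
        return Alignment(list(taxa), [self.rows[index[t]] for t in taxa])

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read a FASTA or NEXUS alignment (format inferred from the file
    when not given)."""
    path = Path(path)
    if fmt is None:
        head = path.read_text()[:200].lstrip()
        fmt = "nexus" if head.upper().startswith("#NEXUS") else "fasta"
    try:
        msa = AlignIO.read(str(path), fmt)
    except Exception as exc:
        raise DataError(f"cannot read {fmt} alignment {path}: {exc}") from exc
    return from_biopython(msa)


def from_biopython(msa: MultipleSeqAlignment) -> Alignment:
    return Alignment([rec.id for rec in msa], [str(rec.seq) for rec in msa])


def classify_sites(aln: Alignment, taxa: Sequence[str] | None = None
                   ) -> "SiteClassification":
    """Count constant, variable-uninformative and parsimony-informative
    sites, optionally over a taxon subset."""
    if taxa is not None:
        aln = aln.subset(taxa)
    constant = uninformative = informative = 0
    for j in range(aln.length):
        states = [c for c in aln.column(j) if c in UNAMBIGUOUS]
        counts = pd.Series(states).value_counts() if states else pd.Series(dtype=int)
        n_states = len(counts)
        if n_states <= 1:
            constant += 1
        elif (counts >= 2).sum() >= 2:
            informative += 1
        else:
            uninformative += 1
    return SiteClassification(aln.length, constant, uninformative, informative)


@dataclass
class SiteClassification:
    included: int
    constant: int
    variable_uninformative: int
    parsimony_informative: int

    def __post_init__(self) -> None:
        total = (self.constant + self.variable_uninformative
                 + self.parsimony_informative)
        if total != self.included:
            raise DataError("site class counts do not sum to included characters")


def _internal_gaps(row: str) -> list[tuple[int, int]]:
    """Maximal '-' runs excluding leading/trailing terminal gaps; spans
    are half-open [start, end) column ranges."""
    n = len(row)
    lead = n - len(row.lstrip("-"))
    trail = n - len(row.rstrip("-"))
    spans = []
    j = lead
    limit = n - trail
    while j < limit:
        if row[j] == "-":
            start = j
            while j < limit and row[j] == "-":
                j += 1
            spans.append((start, j))
        else:
            j += 1
    return spans


@dataclass
class IndelCharacterMatrix:
    """Binary indel characters: one column per distinct internal gap.

    ``states`` is a DataFrame of '0'/'1'/'?' with taxa as the index and
    one column per coded gap; ``spans`` gives each character's half-open
    (start, end) column range.
    """

    states: pd.DataFrame
    spans: list[tuple[int, int]]

    @property
    def n_characters(self) -> int:
        return len(self.spans)

    def informative_characters(self) -> list[int]:
        """Characters with >= 2 taxa scoring 1 and >= 2 scoring 0."""
        out = []
        for k, col in enumerate(self.states.columns):
            vals = self.states[col]
            if (vals == "1").sum() >= 2 and (vals == "0").sum() >= 2:
                out.append(k)
        return out


def simple_indel_coding(aln: Alignment) -> IndelCharacterMatrix:
    """Code each distinct internal gap as a binary character.

    Per character with span [s, e): a taxon scores '1' if it has a gap
    with exactly that start and end, '0' if its sequence is gap-free and
    determined across the span, and '?' if it has a different gap
    overlapping the span, the span lies in its terminal-gap region, or
    the span contains missing data.
    """
    per_taxon = {t: _internal_gaps(r) for t, r in zip(aln.taxa, aln.rows)}
    spans = sorted({g for gaps in per_taxon.values() for g in gaps})
    columns = {}
    for (s, e) in spans:
        states = []
        for t, row in zip(aln.taxa, aln.rows):
            gaps = per_taxon[t]
            if (s, e) in gaps:
                states.append("1")
            elif any(gs < e and ge > s for gs, ge in gaps):
                states.append("?")  # different overlapping gap: ambiguous
            else:
                n = len(row)
                lead = n - len(row.lstrip("-"))
                trail_start = len(row.rstrip("-"))
                segment = row[s:e]
                if s < lead or e > trail_start or any(c in MISSING for c in segment):
                    states.append("?")
                else:
                    states.append("0")
        columns[f"indel_{s + 1}_{e}"] = states
    df = pd.DataFrame(columns, index=aln.taxa, dtype=object) if columns else \
        pd.DataFrame(index=aln.taxa, dtype=object)
    return IndelCharacterMatrix(df, spans)


def marker_summary(alignments: dict[str, Alignment],
                   shared_taxa_only: bool = True) -> pd.DataFrame:
    """Per-marker site statistics, ordered by informative count descending.

    With ``shared_taxa_only`` the counts are made comparable by
    restricting every marker to the taxa present in all markers; the
    taxon subset used is echoed in the ``taxa_used`` column.
    """
    if not alignments:
        raise DataError("no alignments supplied")
    if shared_taxa_only:
        shared = set.intersection(*(set(a.taxa) for a in alignments.values()))
        if not shared:
            raise DataError("no taxa shared across all markers")
        subset = sorted(shared)
    else:
        subset = None
    rows = []
    for name, aln in alignments.items():
        use = aln.subset(subset) if subset else aln
        sc = classify_sites(use)
        indels = simple_indel_coding(use)
        rows.append({"marker": name, "included": sc.included,
                     "variable_uninformative": sc.variable_uninformative,
                     "parsimony_informative": sc.parsimony_informative,
                     "informative_indels": len(indels.informative_characters()),
                     "taxa_used": ";".join(use.taxa)})
    df = pd.DataFrame(rows).sort_values("parsimony_informative",
                                        ascending=False, kind="stable")
    return df.reset_index(drop=True)


def write_nexus_with_indels(aln: Alignment, indels: IndelCharacterMatrix,
                            path: str | Path) -> None:
    """Write the alignment plus a datatype=standard binary indel block."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={aln.n_taxa} NCHAR={aln.length};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        width = max(len(t) for t in aln.taxa) + 2
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f"    {t:<{width}}{r}\n")
        fh.write("  ;\nEND;\n")
        if indels.n_characters:
            fh.write("\nBEGIN CHARACTERS;\n")
            fh.write(f"  DIMENSIONS NCHAR={indels.n_characters};\n")
            fh.write("  FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS=\"01\";\n  MATRIX\n")
            for t in aln.taxa:
                states = "".join(indels.states.loc[t])
                fh.write(f"    {t:<{width}}{states}\n")
            fh.write("  ;\nEND;\n")
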