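"""Protein motif scanning and conserved-column reporting.

Built for delineating carotenoid-oxygenase subfamilies: presence/absence of
the short PDPCK palmitoylation motif (and variants such as SDPCK) and
conservation of the four iron-coordinating histidines across a family
alignment.  Patterns use PROSITE-style syntax; scanning runs on ungapped
sequences and positions are reported 1-based in both ungapped-sequence and
alignment coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .io import AMINO_ACIDS, Phylogeny, ProteinAlignment


class PatternError(ValueError):
    pass


_TOKEN = re.compile(
    r"\[(?P<any>[A-Za-z]+)\]"  # [ABC] alternatives
    r"|\{(?P<none>[A-Za-z]+)\}"  # {ABC} exclusions
    r"|(?P<letter>[A-Za-z])"  # fixed residue or x wildcard
)
_REPEAT = re.compile(r"\((?P<lo>\d+)(?:,(?P<hi>\d+))?\)")


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    pattern: str
    start: int  # 1-based ungapped position of first matched residue
    end: int  # 1-based ungapped position of last matched residue
    aln_start: int  # 1-based alignment column of first matched residue
    aln_end: int
    matched: str
    exact: bool  # pattern was a plain fixed-residue string


def compile_pattern(pattern: str) -> tuple[re.Pattern, bool]:
    """Compile a PROSITE-style motif into a regex over amino-acid strings.

    Supported: fixed letters; ``x`` wildcards; ``[..]`` alternatives;
    ``{..}`` exclusions; ``(n)``/``(n,m)`` repetition after any element;
    optional ``-`` separators.  Returns the regex and whether the pattern is
    exact (fixed residues only, no degeneracy).
    """
    text = pattern.replace("-", "").strip()
    if not text:
        raise PatternError("empty motif pattern")
    out = []
    exact = True
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise PatternError(f"bad motif syntax at {text[pos:]!r} in {pattern!r}")
        pos = m.end()
        if m.group("any"):
            chars = m.group("any").upper()
            _check_residues(chars, pattern)
            piece = f"[{chars}]"
            exact = False
        elif m.group("none"):
            chars = m.group("none").upper()
            _check_residues(chars, pattern)
            piece = f"[^{chars}]"
            exact = False
        else:
            ch = m.group("letter").upper()
            if ch == "X":
                piece = "."
                exact = False
            else:
                _check_residues(ch, pattern)
                piece = ch
        rep = _REPEAT.match(text, pos)
        if rep:
            pos = rep.end()
            lo = rep.group("lo")
            hi = rep.group("hi")
            piece += f"{{{lo}}}" if hi is None else f"{{{lo},{hi}}}"
            if hi is not None:
                exact = False
        out.append(piece)
    return re.compile("".join(out)), exact


def _check_residues(chars: str, pattern: str) -> None:
    bad = [c for c in chars if c not in AMINO_ACIDS]
    if bad:
        raise PatternError(f"non-residue characters {bad} in pattern {pattern!r}")


def _column_maps(row: str) -> list[int]:
    """For each ungapped position (0-based), the 0-based alignment column."""
    return [col for col, ch in enumerate(row) if ch != "-"]


def scan_motif(aln: ProteinAlignment, pattern: str) -> list[MotifHit]:
    """All non-overlapping (leftmost-first) motif matches per sequence."""
    regex, exact = compile_pattern(pattern)
    hits = []
    for name, row in zip(aln.names, aln.rows):
        ungapped = row.replace("-", "")
        cols = _column_maps(row)
        for m in regex.finditer(ungapped):
            if m.end() == m.start():
                continue
            hits.append(
                MotifHit(
                    seq_id=name,
                    pattern=pattern,
                    start=m.start() + 1,
                    end=m.end(),
                    aln_start=cols[m.start()] + 1,
                    aln_end=cols[m.end() - 1] + 1,
                    matched=m.group(0),
                    exact=exact,
                )
            )
    return hits


def conserved_column_report(
    aln: ProteinAlignment, reference: str, positions: list[int]
) -> pd.DataFrame:
    """Residues of every sequence at columns homologous to reference positions.

    ``positions`` are 1-based ungapped positions in the reference sequence
    (the field's residue-numbering convention, e.g. C112 of RPE65).  Gapped
    sequences show '-' and are excluded from the conserved count.
    """
    ref_row = aln.row(reference)
    cols = _column_maps(ref_row)
    records = []
    for pos in positions:
        if not 1 <= pos <= len(cols):
            raise IndexError(
                f"position {pos} beyond ungapped length {len(cols)} of {reference!r}"
            )
        col = cols[pos - 1]
        ref_residue = ref_row[col]
        conserved = 0
        per_seq = {}
        for name, row in zip(aln.names, aln.rows):
            residue = row[col]
            per_seq[name] = residue
            if residue == ref_residue and residue != "-":
                conserved += 1
        for name, residue in per_seq.items():
            records.append(
                {
                    "ref_position": pos,
                    "ref_residue": ref_residue,
                    "alignment_column": col + 1,
                    "sequence": name,
                    "residue": residue,
                    "conserved": residue == ref_residue,
                }
            )
    df = pd.DataFrame(records)
    return df


def conservation_counts(report: pd.DataFrame) -> pd.DataFrame:
    """Summary of the conserved-column report: per position, how many
    sequences retain the reference residue."""
    return (
        report.groupby(["ref_position", "ref_residue", "alignment_column"])
        .agg(n_sequences=("sequence", "size"), n_conserved=("conserved", "sum"))
        .reset_index()
    )


def _is_monophyletic(tree: Phylogeny, leaf_set: frozenset[str]) -> bool:
    below: dict[int, frozenset[str]] = {}
    all_leaves = frozenset(tree.leaf_names)
    for node in tree.postorder():
        if node.is_leaf:
            below[node.index] = frozenset([node.name])
        else:
            below[node.index] = frozenset().union(
                *(below[c.index] for c in node.children)
            )
        if below[node.index] == leaf_set:
            return True
    # a set whose complement hangs from one node is monophyletic when unrooted
    return (all_leaves - leaf_set) in below.values()


def clade_motif_table(
    tree: Phylogeny,
    hits: list[MotifHit],
    clades: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-clade motif presence/absence with a monophyly check.

    ``clades`` maps clade names to leaf-name lists (subsets of the tree's
    leaves).  A sequence counts as motif-positive when it has at least one
    hit in ``hits``.
    """
    leaves = set(tree.leaf_names)
    positive = {h.seq_id for h in hits}
    rows = []
    for clade, members in clades.items():
        unknown = set(members) - leaves
        if unknown:
            raise KeyError(f"clade {clade!r} has leaves not in tree: {sorted(unknown)}")
        n = len(members)
        with_motif = sum(1 for m in members if m in positive)
        rows.append(
            {
                "clade": clade,
                "n": n,
                "n_with_motif": with_motif,
                "fraction": with_motif / n if n else float("nan"),
                "monophyletic": _is_monophyletic(tree, frozenset(members)),
            }
        )
    return pd.DataFrame(rows, columns=["clade", "n", "n_with_motif", "fraction", "monophyletic"])
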