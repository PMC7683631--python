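"""Parsing of molecular-pathology KRAS annotation strings and group labeling.

Annotation grammar (as printed in clinical report summaries):

* missense:      ``G12D (c.35G > A) exon 2`` — protein change, cDNA change,
  exon; whitespace and case tolerant (reports vary).
* amplification: ``Whole gene amplification 12p12.1, FC: 23.0 (Inv. Panel)``
  — cytoband, optional fold change, optional assay-panel suffix.
* wild type:     empty/blank string (or literal "wild type").

Two grouping policies convert annotations into binary labels for the
separation analyses: missense mutations are always the positive class; the
few whole-gene amplification cases are grouped either with wild type
(``amp_with_wt``, the primary analysis — amplification is mutually exclusive
with missense mutation and its clinical significance differs) or with the
mutants (``amp_with_mut``, the sensitivity analysis).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

_MISSENSE_RE = re.compile(
    r"^\s*([A-Z])\s*(\d+)\s*([A-Z])\s*"
    r"\(\s*c\.\s*(\d+)\s*([ACGT])\s*>\s*([ACGT])\s*\)\s*"
    r"exon\s*(\d+)\s*$",
    re.IGNORECASE,
)

_AMP_RE = re.compile(
    r"^\s*whole\s+gene\s+amplification\s*([\dXYpq.]+)?\s*"
    r"(?:,\s*FC\s*:\s*(\d+(?:\.\d+)?))?\s*"
    r"(?:\(\s*(.*?)\s*\))?\s*$",
    re.IGNORECASE,
)

_WT_RE = re.compile(r"^\s*(wild[\s-]?type)?\s*$", re.IGNORECASE)


@dataclass(frozen=True)
class KrasAnnotation:
    """Parsed molecular result for one case."""

    raw: str
    kind: str  # {"missense", "amplification", "wild_type"}
    codon: int | None = None
    aa_change: str | None = None
    cdna_change: str | None = None
    exon: int | None = None
    cytoband: str | None = None
    fold_change: float | None = None
    panel: str | None = None

    def format(self) -> str:
        """Canonical string form; ``parse_annotation(ann.format())`` round-trips."""
        if self.kind == "wild_type":
            return ""
        if self.kind == "missense":
            return f"{self.aa_change} ({self.cdna_change}) exon {self.exon}"
        parts = [f"Whole gene amplification {self.cytoband or ''}".rstrip()]
        if self.fold_change is not None:
            parts.append(f"FC: {self.fold_change:g}")
        s = ", ".join(parts)
        if self.panel:
            s += f" ({self.panel})"
        return s


def parse_annotation(raw: str | None) -> KrasAnnotation:
    """Parse one annotation string.

    Unrecognized non-empty strings raise ``ValueError`` naming the offending
    value — an unparseable report must never silently become wild type.
    """
    text = "" if raw is None else str(raw)
    m = _MISSENSE_RE.match(text)
    if m:
        ref_aa, codon, alt_aa, pos, ref_nt, alt_nt = m.group(1, 2, 3, 4, 5, 6)
        return KrasAnnotation(
            raw=text,
            kind="missense",
            codon=int(codon),
            aa_change=f"{ref_aa.upper()}{int(codon)}{alt_aa.upper()}",
            cdna_change=f"c.{int(pos)}{ref_nt.upper()} > {alt_nt.upper()}",
            exon=int(m.group(7)),
        )
    m = _AMP_RE.match(text)
    if m:
        fc = m.group(2)
        return KrasAnnotation(
            raw=text,
            kind="amplification",
            cytoband=m.group(1),
            fold_change=float(fc) if fc is not None else None,
            panel=m.group(3),
        )
    if _WT_RE.match(text):
        return KrasAnnotation(raw=text, kind="wild_type")
    raise ValueError(f"unrecognized KRAS annotation: {text!r}")


POLICIES = ("amp_with_wt", "amp_with_mut")


def assign_labels(
    annotations: Sequence[KrasAnnotation | str], policy: str = "amp_with_wt"
) -> list[int]:
    """Binary labels (1 = treated as KRAS-positive) under a grouping policy."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    labels = []
    for ann in annotations:
        if isinstance(ann, str):
            ann = parse_annotation(ann)
        if ann.kind == "missense":
            labels.append(1)
        elif ann.kind == "amplification":
            labels.append(1 if policy == "amp_with_mut" else 0)
        else:
            labels.append(0)
    return labels


def codon_census(annotations: Iterable[KrasAnnotation | str]) -> dict[int, int]:
    """Histogram of missense codons; amplifications and wild type are excluded."""
    counts: Counter[int] = Counter()
    for ann in annotations:
        if isinstance(ann, str):
            ann = parse_annotation(ann)
        if ann.kind == "missense":
            counts[ann.codon] += 1
    return dict(sorted(counts.items()))


def concordance_percent(n_concordant: int, n_genotyped_pairs: int) -> float:
    """Percent concordance between paired primary/metastasis genotypes."""
    if n_genotyped_pairs <= 0:
        raise ValueError("need at least one genotyped pair")
    return 100.0 * n_concordant / n_genotyped_pairs


def expected_mislabeled(
    n_lesions: int, n_confirmed: int, discordance_rate: float = 0.10
) -> float:
    """Expected number of mislabeled lesions when only some were directly genotyped.

    Lesions whose status came from the targeted biopsy are assumed correct;
    the rest inherit the patient-level status and carry the primary-to-
    metastasis discordance rate.
    """
    if n_confirmed > n_lesions:
        raise ValueError("confirmed lesions cannot exceed total lesions")
    return discordance_rate * (n_lesions - n_confirmed)
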