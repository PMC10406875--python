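"""In-silico PCR, dominant-marker sex calling, and panel accuracy scoring.

A primer binds the plus strand where it matches left-to-right with at most
``max_mismatches`` substitutions, and the minus strand where its reverse
complement matches — in both cases the primer's 3'-terminal base must match
exactly, since a 3' mismatch abolishes polymerase extension. An amplicon is
predicted for every forward-site/reverse-site combination in productive
orientation whose product length falls within [min_product_size,
max_product_size]. Annealing temperature is carried as metadata only.

A dominant marker is scored per individual as presence (>= 1 predicted
amplicon on any template: call male) or absence (call female). Panel accuracy
is the percentage of males with presence plus females with absence, printed
half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .io import revcomp

#: primer pairs printed in the source study (name -> forward, reverse, Tm °C, band bp)
PUBLISHED_PRIMERS: dict[str, tuple[str, str, float, int]] = {
    "P51": ("TCTTCCTCTTGGTGCCCG", "TCAAAGAACCGCTAATCCCAT", 60.0, 609),
    "P11": ("TCTCGCCATCTTCAACCATTT", "ATCTTGGCGTATCTCGGCTTT", 65.0, 304),
}


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    annealing_temp: float | None = None
    expected_size: int | None = None
    marker_type: str = "dominant"

    def __post_init__(self) -> None:
        for primer in (self.forward, self.reverse):
            if len(primer) < 15 or set(primer) - set("ACGT"):
                raise ValueError(f"{self.name}: primers must be >= 15 bases of A/C/G/T")


def published_primer_pairs() -> list[PrimerPair]:
    return [
        PrimerPair(name, fwd, rev, tm, size)
        for name, (fwd, rev, tm, size) in PUBLISHED_PRIMERS.items()
    ]


@dataclass(frozen=True)
class PcrParams:
    max_mismatches: int = 0
    max_product_size: int = 5000
    min_product_size: int = 50

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not self.min_product_size < self.max_product_size:
            raise ValueError("min_product_size must be < max_product_size")


@dataclass(frozen=True)
class PrimerSite:
    position: int  # 0-based start of the matched window on the template
    strand: str  # "+" primer binds the plus strand, "-" the minus strand


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    start: int  # 0-based inclusive, template coordinates
    end: int  # 0-based exclusive
    sequence: str  # oriented forward-primer-first
    strand: str  # "+" forward primer on plus strand, "-" on minus strand

    @property
    def length(self) -> int:
        return self.end - self.start


def _matches(window: str, primer: str, max_mismatches: int) -> bool:
    """Window matches primer with <= max_mismatches, 3' base anchored exact."""
    if len(window) != len(primer):
        return False
    if window[-1] != primer[-1]:
        return False
    mismatches = sum(a != b for a, b in zip(window, primer))
    return mismatches <= max_mismatches


def find_primer_sites(template: str, primer: str, params: PcrParams) -> list[PrimerSite]:
    """All binding sites of a primer on both strands of a template.

    A minus-strand site is reported at the template position where the
    reverse complement of the primer begins; the primer's 3' end then faces
    the template's 5' direction.
    """
    n, p = len(template), len(primer)
    sites: list[PrimerSite] = []
    if params.max_mismatches == 0:
        for pos in _find_all(template, primer):
            sites.append(PrimerSite(pos, "+"))
        for pos in _find_all(template, revcomp(primer)):
            sites.append(PrimerSite(pos, "-"))
    else:
        rc = revcomp(primer)
        for pos in range(n - p + 1):
            window = template[pos : pos + p]
            if _matches(window, primer, params.max_mismatches):
                sites.append(PrimerSite(pos, "+"))
            # minus-strand binding: primer matches revcomp(window) read 3'->5' on plus,
            # i.e. revcomp(primer) matches the window with the anchor at window start
            if _matches(revcomp(window), primer, params.max_mismatches):
                sites.append(PrimerSite(pos, "-"))
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def _find_all(text: str, pattern: str) -> list[int]:
    hits, pos = [], text.find(pattern)
    while pos != -1:
        hits.append(pos)
        pos = text.find(pattern, pos + 1)
    return hits


def predict_amplicons(
    template: str,
    pair: PrimerPair,
    params: PcrParams = PcrParams(),
    template_id: str = "template",
) -> list[AmpliconPrediction]:
    """Every productive forward/reverse site combination within the size band.

    Both orientations of the product are searched: forward primer on the plus
    strand with the reverse primer downstream on the minus strand, and the
    mirror image (reported reverse-complemented so the returned sequence
    always starts with the forward primer). Sorted by template start.
    """
    fwd_sites = find_primer_sites(template, pair.forward, params)
    rev_sites = find_primer_sites(template, pair.reverse, params)
    out: list[AmpliconPrediction] = []
    # orientation 1: forward on plus strand, reverse on minus strand downstream
    for f in (s for s in fwd_sites if s.strand == "+"):
        for r in (s for s in rev_sites if s.strand == "-"):
            start = f.position
            end = r.position + len(pair.reverse)
            if start + len(pair.forward) > r.position:
                continue  # sites overlap or reversed
            length = end - start
            if params.min_product_size <= length <= params.max_product_size:
                out.append(
                    AmpliconPrediction(template_id, start, end, template[start:end], "+")
                )
    # orientation 2: forward on minus strand, reverse on plus strand upstream
    for f in (s for s in fwd_sites if s.strand == "-"):
        for r in (s for s in rev_sites if s.strand == "+"):
            start = r.position
            end = f.position + len(pair.forward)
            if start + len(pair.reverse) > f.position:
                continue
            length = end - start
            if params.min_product_size <= length <= params.max_product_size:
                out.append(
                    AmpliconPrediction(
                        template_id, start, end, revcomp(template[start:end]), "-"
                    )
                )
    out.sort(key=lambda a: (a.start, a.end, a.strand))
    return out


def call_sex(
    templates: Iterable[tuple[str, str]],
    pair: PrimerPair,
    params: PcrParams = PcrParams(),
) -> str:
    """Dominant-marker call over an individual's template set.

    "presence" (>= 1 amplicon on any template) means the Y-linked site is
    there: the individual is called male; "absence" calls female.
    """
    templates = list(templates)
    if not templates:
        raise ValueError("template set is empty")
    for seq_id, seq in templates:
        if predict_amplicons(seq, pair, params, template_id=seq_id):
            return "presence"
    return "absence"


PREDICTED_SEX = {"presence": "male", "absence": "female"}


@dataclass
class PanelResult:
    """Per-individual calls plus the grouped contingency table and accuracy."""

    rows: pd.DataFrame  # individual_id, sex, subpopulation, call, predicted_sex, correct
    contingency: pd.DataFrame  # sex, subpopulation, presence, absence
    accuracy_rate: float  # percent, half-up to 2 decimals
    n: int


def _round_percent(numerator: int, denominator: int) -> float:
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def score_panel(calls: Mapping[str, str], truth: pd.DataFrame) -> PanelResult:
    """Score presence/absence calls against known sexes, Table-2 style.

    ``truth`` needs columns individual_id and sex ("male"/"female"); an
    optional subpopulation column groups the contingency table. Accuracy is
    100 x (males with presence + females with absence) / n.
    """
    truth = truth.copy()
    if "subpopulation" not in truth.columns:
        truth["subpopulation"] = "all"
    truth_ids = set(truth["individual_id"])
    call_ids = set(calls)
    if truth_ids != call_ids:
        orphans = sorted(truth_ids ^ call_ids)
        raise ValueError(f"calls and truth disagree on individuals: {orphans}")
    bad = sorted(set(calls.values()) - {"presence", "absence"})
    if bad:
        raise ValueError(f"calls must be 'presence' or 'absence', got {bad}")

    rows = truth[["individual_id", "sex", "subpopulation"]].copy()
    rows["call"] = rows["individual_id"].map(calls)
    rows["predicted_sex"] = rows["call"].map(PREDICTED_SEX)
    rows["correct"] = rows["predicted_sex"] == rows["sex"]

    contingency = (
        rows.groupby(["sex", "subpopulation", "call"], sort=True)
        .size()
        .unstack("call", fill_value=0)
        .reindex(columns=["presence", "absence"], fill_value=0)
        .reset_index()
    )
    contingency.columns.name = None

    n = len(rows)
    accuracy = _round_percent(int(rows["correct"].sum()), n) if n else 0.0
    return PanelResult(rows, contingency, accuracy, n)


def expand_contingency(
    groups: Iterable[tuple[str, str, int, int]],
) -> tuple[dict[str, str], pd.DataFrame]:
    """Turn printed contingency counts into per-individual calls and truth.

    Each group is (sex, subpopulation, n_presence, n_absence). Useful for
    re-scoring a published contingency table through score_panel.
    """
    calls: dict[str, str] = {}
    rows = []
    for gi, (sex, subpop, n_presence, n_absence) in enumerate(groups):
        for i in range(n_presence + n_absence):
            ind = f"g{gi}_{sex}_{subpop}_{i + 1:03d}"
            calls[ind] = "presence" if i < n_presence else "absence"
            rows.append({"individual_id": ind, "sex": sex, "subpopulation": subpop})
    return calls, pd.DataFrame(rows, columns=["individual_id", "sex", "subpopulation"])


def amplicon_table(amplicons: Iterable[AmpliconPrediction], primer_name: str) -> pd.DataFrame:
    """BED-like frame of predictions (1-based inclusive start in reports)."""
    rows = [
        {
            "template_id": a.template_id,
            "start": a.start + 1,
            "end": a.end,
            "length": a.length,
            "primer_name": primer_name,
            "strand": a.strand,
        }
        for a in amplicons
    ]
    return pd.DataFrame(
        rows, columns=["template_id", "start", "end", "length", "primer_name", "strand"]
    )
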