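"""Sample-level QC: sex chromosome complement inference and exclusion rules.

The complement call uses expression of five Y-linked marker genes
(EIF1AY, KDM5D, UTY, DDX3Y, RPS4Y1) and XIST: a sample carrying a Y
chromosome expresses most or all of the Y markers, while a sample with
two X chromosomes expresses XIST. Exclusion applies a post-trim read
count window, a per-sequence GC deviation cap, and agreement between the
inferred complement and the reported sex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .simulate import XIST, Y_MARKERS

__all__ = [
    "SampleQCRecord",
    "SexComplementCall",
    "infer_sex_complement",
    "apply_qc_filters",
]

MIN_READS = 12_500_000
MAX_READS = 90_000_000
MAX_GC_FRACTION = 0.30


@dataclass(frozen=True)
class SampleQCRecord:
    sample: str
    reads_post_trim: int
    gc_deviation_fraction: float
    reported_sex: str = "unknown"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_deviation_fraction <= 1.0:
            raise ValueError(
                f"gc_deviation_fraction out of [0,1] for {self.sample!r}"
            )


@dataclass(frozen=True)
class SexComplementCall:
    sample: str
    call: str  # XX_like | XY_like | ambiguous
    y_markers_expressed: int
    xist_cpm: float
    evidence: Mapping[str, float]


def infer_sex_complement(
    marker_cpm: pd.DataFrame,
    y_cpm_threshold: float = 1.0,
    xist_cpm_threshold: float = 10.0,
) -> list[SexComplementCall]:
    """Call XX_like / XY_like / ambiguous per sample from marker CPM.

    ``marker_cpm`` is samples x markers and must contain the five Y
    markers and XIST. XY_like needs >= 4 of 5 Y markers above
    ``y_cpm_threshold``; XX_like needs <= 1 Y marker above threshold and
    XIST above ``xist_cpm_threshold``; anything else (e.g. all markers
    silent) is ambiguous.
    """
    if y_cpm_threshold <= 0 or xist_cpm_threshold <= 0:
        raise ValueError("thresholds must be positive")
    needed = list(Y_MARKERS) + [XIST]
    calls = []
    for sample, row in marker_cpm.iterrows():
        for m in needed:
            if m not in row.index or pd.isna(row[m]):
                raise ValueError(f"sample {sample!r} is missing marker {m!r}")
        n_y = int(sum(row[m] > y_cpm_threshold for m in Y_MARKERS))
        xist = float(row[XIST])
        if n_y >= 4:
            call = "XY_like"
        elif n_y <= 1 and xist > xist_cpm_threshold:
            call = "XX_like"
        else:
            call = "ambiguous"
        calls.append(
            SexComplementCall(
                sample=str(sample),
                call=call,
                y_markers_expressed=n_y,
                xist_cpm=xist,
                evidence={m: float(row[m]) for m in needed},
            )
        )
    return calls


_CALL_TO_SEX = {"XX_like": "female", "XY_like": "male"}


def apply_qc_filters(
    records: Sequence[SampleQCRecord],
    calls: Sequence[SexComplementCall],
    min_reads: int = MIN_READS,
    max_reads: int = MAX_READS,
    max_gc_fraction: float = MAX_GC_FRACTION,
    replicate_groups: Mapping[str, str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the exclusion rules; reasons are exhaustive per sample.

    A sample is excluded iff its post-trim reads fall outside
    ``[min_reads, max_reads]``, its GC deviation fraction exceeds
    ``max_gc_fraction``, or its inferred complement disagrees with the
    reported sex (an ambiguous call counts as a mismatch when a sex was
    reported). When ``replicate_groups`` maps samples to biological
    groups, excluding any member removes the whole group (reason
    ``replicate_excluded`` for the others).

    Returns (kept sample ids, exclusion table with ';'-joined reasons).
    """
    call_by_sample = {c.sample: c for c in calls}
    reasons: dict[str, list[str]] = {}
    for rec in records:
        if rec.sample not in call_by_sample:
            raise ValueError(f"no sex-complement call for sample {rec.sample!r}")
        r = []
        if rec.reads_post_trim < min_reads:
            r.append("low_reads")
        if rec.reads_post_trim > max_reads:
            r.append("high_reads")
        if rec.gc_deviation_fraction > max_gc_fraction:
            r.append("gc_content")
        call = call_by_sample[rec.sample]
        if rec.reported_sex in ("female", "male"):
            if _CALL_TO_SEX.get(call.call) != rec.reported_sex:
                r.append("sex_mismatch")
        reasons[rec.sample] = r
    if replicate_groups is not None:
        failed_groups = {
            replicate_groups[s] for s, r in reasons.items() if r and s in replicate_groups
        }
        for s in reasons:
            grp = replicate_groups.get(s)
            if grp in failed_groups and not reasons[s]:
                reasons[s].append("replicate_excluded")
    kept = [s for s, r in reasons.items() if not r]
    excl = pd.DataFrame(
        [
            {"sample": s, "reasons": ";".join(r)}
            for s, r in reasons.items()
            if r
        ],
        columns=["sample", "reasons"],
    ).set_index("sample")
    return kept, excl
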