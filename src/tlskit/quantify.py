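"""TLS extent quantification from colony counts and clone classifications.

The assay co-transfects a gap-lesion plasmid (kanamycin marker) with a
lesion-free control gapped plasmid (chloramphenicol marker).  The ratio of
kanR to cmR bacterial transformants measures plasmid repair; multiplying by
the sequencing-derived fraction of TLS events among repair events gives the
TLS extent, reported as a percentage.  Extents are expressed relative to an
isogenic wild-type reference condition, with per-replicate pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .classification import Category, EventClassification, summarize_spectrum

__all__ = [
    "QuantificationError",
    "ConditionCounts",
    "TlsQuantification",
    "plasmid_repair_extent",
    "tls_extent",
    "mutagenic_frequency",
    "quantify_condition",
    "relative_tls",
    "fold_change",
    "quantify",
]

#: below this many scored clones per replicate the TLS fraction is pooled
#: across replicates instead of estimated per replicate
MIN_CLONES_PER_REPLICATE = 20


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class ConditionCounts:
    """Colony counts for one condition/replicate."""

    condition_id: str
    replicate_id: str
    kanR: int
    cmR: int

    def __post_init__(self) -> None:
        if self.kanR < 0 or self.cmR < 0:
            raise QuantificationError(
                f"{self.condition_id}/{self.replicate_id}: negative colony count"
            )


def plasmid_repair_extent(counts: ConditionCounts) -> float:
    """kanR/cmR colony ratio — the fraction of gap-lesion plasmids repaired."""
    if counts.cmR == 0:
        raise QuantificationError(
            f"{counts.condition_id}/{counts.replicate_id}: cmR = 0, repair extent undefined"
        )
    return counts.kanR / counts.cmR


def tls_extent(repair_extent: float, fraction_tls: float) -> float:
    """Percent TLS: plasmid repair extent times the TLS fraction of repair events."""
    if not 0.0 <= fraction_tls <= 1.0:
        raise QuantificationError(f"fraction_tls {fraction_tls} outside [0, 1]")
    if repair_extent < 0.0:
        raise QuantificationError(f"repair_extent {repair_extent} negative")
    return 100.0 * repair_extent * fraction_tls


def mutagenic_frequency(events: list[EventClassification]) -> float:
    """Percent of TLS events that are not accurate (NON_TLS/UNSCORABLE excluded)."""
    spectrum = summarize_spectrum(events)
    if spectrum.mutagenic_pct is None:
        raise QuantificationError("mutagenic_frequency: no TLS events in input")
    return spectrum.mutagenic_pct


def _mean_sd(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, math.nan
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


@dataclass
class TlsQuantification:
    """Per-condition repair and TLS extents, averaged over replicates."""

    condition_id: str
    n_replicates: int
    repair_extent: float
    repair_extent_sd: float
    fraction_tls: float
    tls_extent: float          # percent
    tls_extent_sd: float
    mutagenic_pct: float | None
    pooled_fraction: bool
    per_replicate: dict[str, dict[str, float]] = field(default_factory=dict)
    relative_tls: float | None = None
    relative_tls_sd: float | None = None
    fold_vs_reference: float | None = None


def quantify_condition(
    counts: list[ConditionCounts],
    events: list[EventClassification],
) -> TlsQuantification:
    """Combine colony counts and clone classifications for one condition.

    The TLS fraction is estimated per replicate when every replicate has at
    least ``MIN_CLONES_PER_REPLICATE`` scored clones, otherwise pooled
    across replicates (``pooled_fraction`` flags which was done).
    """
    if not counts:
        raise QuantificationError("quantify_condition: no colony counts")
    if not events:
        raise QuantificationError("quantify_condition: no classified clones")
    cond = counts[0].condition_id
    if any(c.condition_id != cond for c in counts) or any(
        e.condition_id not in ("", cond) for e in events
    ):
        raise QuantificationError(f"quantify_condition: mixed condition ids (expected {cond})")

    pooled = summarize_spectrum(events)
    if pooled.fraction_tls is None:
        raise QuantificationError(f"{cond}: no scorable clones")

    by_rep: dict[str, list[EventClassification]] = {}
    for e in events:
        by_rep.setdefault(e.replicate_id, []).append(e)

    rep_spectra = {r: summarize_spectrum(ev) for r, ev in by_rep.items()}
    use_pooled = any(
        c.replicate_id not in rep_spectra
        or rep_spectra[c.replicate_id].n_scored < MIN_CLONES_PER_REPLICATE
        for c in counts
    )

    per_rep: dict[str, dict[str, float]] = {}
    repair_vals, extent_vals = [], []
    for c in counts:
        repair = plasmid_repair_extent(c)
        if use_pooled:
            ftls = pooled.fraction_tls
        else:
            ftls = rep_spectra[c.replicate_id].fraction_tls
        ext = tls_extent(repair, ftls)
        per_rep[c.replicate_id] = {
            "repair_extent": repair,
            "fraction_tls": ftls,
            "tls_extent": ext,
        }
        repair_vals.append(repair)
        extent_vals.append(ext)

    repair_mean, repair_sd = _mean_sd(repair_vals)
    ext_mean, ext_sd = _mean_sd(extent_vals)
    return TlsQuantification(
        condition_id=cond,
        n_replicates=len(counts),
        repair_extent=repair_mean,
        repair_extent_sd=repair_sd,
        fraction_tls=pooled.fraction_tls,
        tls_extent=ext_mean,
        tls_extent_sd=ext_sd,
        mutagenic_pct=pooled.mutagenic_pct,
        pooled_fraction=use_pooled,
        per_replicate=per_rep,
    )


def relative_tls(
    condition: TlsQuantification, reference: TlsQuantification
) -> tuple[float, float]:
    """Condition TLS extent as a percentage of the reference, per replicate.

    Replicates are paired by id where possible; with disjoint replicate
    ids each condition replicate is expressed relative to the reference
    mean.  Returns (mean, sd) over replicates; the reference condition
    itself maps to (100, 0) by construction when paired with itself.
    """
    shared = sorted(set(condition.per_replicate) & set(reference.per_replicate))
    if shared:
        ref_ext = [reference.per_replicate[r]["tls_extent"] for r in shared]
        cond_ext = [condition.per_replicate[r]["tls_extent"] for r in shared]
        if any(e == 0 for e in ref_ext):
            raise QuantificationError(
                f"relative_tls: reference {reference.condition_id} has a zero-extent replicate"
            )
        rel = [100.0 * c / r for c, r in zip(cond_ext, ref_ext)]
    else:
        if reference.tls_extent == 0:
            raise QuantificationError(
                f"relative_tls: reference {reference.condition_id} extent is zero"
            )
        rel = [
            100.0 * v["tls_extent"] / reference.tls_extent
            for v in condition.per_replicate.values()
        ]
    return _mean_sd(rel)


def fold_change(reference: TlsQuantification, condition: TlsQuantification) -> float:
    """Reference-to-condition ratio of mean TLS extents (4.4 = 4.4-fold lower)."""
    if condition.tls_extent == 0:
        raise QuantificationError(f"fold_change: {condition.condition_id} extent is zero")
    return reference.tls_extent / condition.tls_extent


def quantify(
    counts_df: pd.DataFrame,
    events: list[EventClassification],
    reference_condition: str | None = None,
) -> dict[str, TlsQuantification]:
    """Quantify every condition in a counts table.

    ``counts_df`` needs columns condition_id, replicate_id, kanR, cmR.
    When ``reference_condition`` is given, relative TLS and fold-change
    versus that condition are filled in for every condition.
    """
    required = {"condition_id", "replicate_id", "kanR", "cmR"}
    missing = required - set(counts_df.columns)
    if missing:
        raise QuantificationError(f"counts table missing columns: {sorted(missing)}")
    by_cond_events: dict[str, list[EventClassification]] = {}
    for e in events:
        by_cond_events.setdefault(e.condition_id, []).append(e)

    out: dict[str, TlsQuantification] = {}
    for cond, grp in counts_df.groupby("condition_id", sort=True):
        cond = str(cond)
        if cond not in by_cond_events:
            raise QuantificationError(f"no classified clones for condition {cond}")
        counts = [
            ConditionCounts(cond, str(r.replicate_id), int(r.kanR), int(r.cmR))
            for r in grp.itertuples()
        ]
        out[cond] = quantify_condition(counts, by_cond_events[cond])

    if reference_condition is not None:
        if reference_condition not in out:
            raise QuantificationError(f"reference condition {reference_condition} not in counts")
        ref = out[reference_condition]
        for q in out.values():
            q.relative_tls, q.relative_tls_sd = relative_tls(q, ref)
            q.fold_vs_reference = fold_change(ref, q)
    return out
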