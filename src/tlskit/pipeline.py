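"""End-to-end pipeline: classify -> quantify -> compare -> report bundle."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import io as tio
from .classification import (
    EventClassification,
    classify_read,
    make_aligner,
    summarize_spectrum,
)
from .constructs import CloneRead, LesionConstruct, default_constructs, load_constructs
from .quantify import TlsQuantification, quantify
from .stats import compare_spectra

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "classify_dataset"]

log = logging.getLogger("tlskit")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    fasta: Path
    manifest: Path
    counts: Path
    out_dir: Path
    constructs_path: Path | None = None
    references: dict[str, str] = field(default_factory=dict)  # construct_id -> condition_id
    align_params: dict[str, float] = field(default_factory=dict)
    test_method: str = "auto"

    def __post_init__(self) -> None:
        for name in ("fasta", "manifest", "counts"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        self.out_dir = Path(self.out_dir)
        if self.constructs_path is not None:
            self.constructs_path = Path(self.constructs_path)
            if not self.constructs_path.exists():
                raise FileNotFoundError(f"constructs config not found: {self.constructs_path}")


def classify_dataset(
    fasta: Path,
    manifest: Path,
    constructs: list[LesionConstruct],
    align_params: dict[str, float] | None = None,
) -> list[EventClassification]:
    """Classify every clone in a FASTA against its manifest-assigned construct."""
    reads = dict(tio.read_fasta(fasta))
    man = tio.read_manifest(manifest)
    by_id = {c.id: c for c in constructs}
    aligner = make_aligner(**(align_params or {}))
    events = []
    for row in man.itertuples():
        if row.clone_id not in reads:
            raise PipelineError(f"classify: clone {row.clone_id!r} in manifest but not FASTA")
        if row.construct_id not in by_id:
            raise PipelineError(
                f"classify: clone {row.clone_id!r} references unknown construct "
                f"{row.construct_id!r}"
            )
        read = CloneRead(row.clone_id, row.condition_id, row.replicate_id, reads[row.clone_id])
        events.append(classify_read(read, by_id[row.construct_id], aligner))
    extra = set(reads) - set(man["clone_id"])
    if extra:
        log.warning("classify: %d FASTA records absent from manifest ignored", len(extra))
    return events


def events_to_frame(events: list[EventClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "clone_id": [e.clone_id for e in events],
            "condition_id": [e.condition_id for e in events],
            "replicate_id": [e.replicate_id for e in events],
            "category": [e.category.value for e in events],
            "is_tls": [str(e.is_tls) for e in events],
            "observed_window": [e.observed_window for e in events],
            "edit_summary": [e.edit_summary for e in events],
            "anchor_identity": [f"{e.anchor_identity:.4f}" for e in events],
        }
    )


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.6g}"


def _quant_row(q: TlsQuantification) -> dict:
    return {
        "condition_id": q.condition_id,
        "n_replicates": q.n_replicates,
        "repair_extent": _fmt(q.repair_extent),
        "repair_extent_sd": _fmt(q.repair_extent_sd),
        "fraction_tls": _fmt(q.fraction_tls),
        "tls_extent_pct": _fmt(q.tls_extent),
        "tls_extent_sd": _fmt(q.tls_extent_sd),
        "relative_tls_pct": _fmt(q.relative_tls),
        "relative_tls_sd": _fmt(q.relative_tls_sd),
        "fold_vs_reference": _fmt(q.fold_vs_reference),
        "mutagenic_pct": _fmt(q.mutagenic_pct),
        "pooled_fraction": str(q.pooled_fraction),
    }


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute classify -> quantify -> compare and write the report bundle.

    Outputs under ``cfg.out_dir``: clones.tsv (per-clone calls),
    spectrum.tsv, quantification.tsv, quantification.json, comparisons.tsv
    and summary.txt.  Deterministic: identical inputs give byte-identical
    outputs.
    """
    constructs = (
        load_constructs(cfg.constructs_path) if cfg.constructs_path else default_constructs()
    )
    events = classify_dataset(cfg.fasta, cfg.manifest, constructs, cfg.align_params)
    man = tio.read_manifest(cfg.manifest)
    cond_construct = dict(zip(man["condition_id"], man["construct_id"]))
    counts_df = tio.read_counts(cfg.counts)

    n_unscorable = sum(1 for e in events if not e.is_tls and e.category.value == "UNSCORABLE")
    log.info("classified %d clones (%d unscorable)", len(events), n_unscorable)

    # quantify per construct group so relative TLS stays within one lesion
    by_construct: dict[str, list[str]] = {}
    for cond, cid in cond_construct.items():
        by_construct.setdefault(cid, [])
        if cond not in by_construct[cid]:
            by_construct[cid].append(cond)
    quants: dict[str, TlsQuantification] = {}
    for cid, conds in sorted(by_construct.items()):
        sub = counts_df[counts_df["condition_id"].isin(conds)]
        sub_events = [e for e in events if e.condition_id in conds]
        ref = cfg.references.get(cid)
        quants.update(quantify(sub, sub_events, reference_condition=ref))
    for q in quants.values():
        if q.pooled_fraction:
            log.info("%s: TLS fraction pooled across replicates", q.condition_id)

    # spectra per condition
    by_cond: dict[str, list[EventClassification]] = {}
    for e in events:
        by_cond.setdefault(e.condition_id, []).append(e)
    spec_rows = []
    for cond in sorted(by_cond):
        s = summarize_spectrum(by_cond[cond])
        row = {"condition_id": cond, "n_clones": s.n_clones, "n_scored": s.n_scored,
               "fraction_tls": _fmt(s.fraction_tls), "mutagenic_pct": _fmt(s.mutagenic_pct)}
        for cat, cnt in s.category_counts.items():
            row[f"n_{cat}"] = cnt
        for cat in ("ACCURATE", "TARGETED", "SEMI_TARGETED", "MIXED"):
            row[f"pct_{cat}"] = _fmt(s.tls_category_pct[cat] if s.tls_category_pct else None)
        spec_rows.append(row)

    # pairwise spectrum comparisons within each construct group
    cmp_rows = []
    for cid, conds in sorted(by_construct.items()):
        for a, b in combinations(sorted(conds), 2):
            try:
                cmpres = compare_spectra(by_cond[a], by_cond[b], method=cfg.test_method)
            except ValueError as exc:
                raise PipelineError(f"compare: {a} vs {b}: {exc}") from exc
            cmp_rows.append(
                {"construct_id": cid, "condition_a": a, "condition_b": b,
                 "acc_a": cmpres.table[0][0], "mut_a": cmpres.table[0][1],
                 "acc_b": cmpres.table[1][0], "mut_b": cmpres.table[1][1],
                 "statistic": _fmt(cmpres.statistic), "p_value": _fmt(cmpres.p_value),
                 "method": cmpres.method}
            )

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "clones": out / "clones.tsv",
        "spectrum": out / "spectrum.tsv",
        "quantification_tsv": out / "quantification.tsv",
        "quantification_json": out / "quantification.json",
        "comparisons": out / "comparisons.tsv",
        "summary": out / "summary.txt",
    }
    tio.write_tsv(events_to_frame(events), paths["clones"])
    tio.write_tsv(pd.DataFrame(spec_rows), paths["spectrum"])
    quant_rows = [_quant_row(quants[c]) for c in sorted(quants)]
    tio.write_tsv(pd.DataFrame(quant_rows), paths["quantification_tsv"])
    json_payload = {
        c: {
            k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in vars(quants[c]).items()
        }
        for c in sorted(quants)
    }
    paths["quantification_json"].write_text(
        json.dumps(json_payload, indent=2, sort_keys=True) + "\n"
    )
    tio.write_tsv(pd.DataFrame(cmp_rows), paths["comparisons"])

    lines = [
        f"conditions: {len(quants)}",
        f"clones classified: {len(events)}",
        f"unscorable clones: {sum(1 for e in events if e.category.value == 'UNSCORABLE')}",
        "",
    ]
    for c in sorted(quants):
        q = quants[c]
        lines.append(
            f"{c}: repair {q.repair_extent:.3f}, TLS extent {q.tls_extent:.2f}% "
            f"(sd {_fmt(q.tls_extent_sd)}), mutagenic {_fmt(q.mutagenic_pct)}%"
            + (f", relative {q.relative_tls:.1f}%" if q.relative_tls is not None else "")
        )
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
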