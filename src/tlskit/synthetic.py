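"""Ground-truth simulator for the gap-lesion plasmid assay.

Emulates the sampling structure of the assay so that every pipeline stage
can be tested against known truth:

* colony counts — kanR ~ Poisson(n_effective x p_repair_lesion) and
  cmR ~ Poisson(n_effective x p_repair_control) per replicate, reflecting
  count noise in bacterial transformation;
* clone categories — multinomial draws from a ground-truth spectrum over
  {ACCURATE, TARGETED, SEMI_TARGETED, MIXED, DEL1, NON_TLS};
* sequences — category-specific edits applied to the construct reference:
  substitutions opposite/flanking the lesion, a single-nucleotide deletion
  at a lesion-opposite position (DEL1), or a large deletion spanning the
  window (NON_TLS, default 10-50 nt).

One RNG stream is derived per (seed, condition, replicate), so adding a
condition never perturbs the draws of another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .constructs import CloneRead, LesionConstruct, default_constructs
from .quantify import ConditionCounts

__all__ = [
    "TRUTH_CATEGORIES",
    "ConditionTruth",
    "GroundTruthConfig",
    "SimulatedCondition",
    "simulate_condition",
    "simulate_study",
    "simulate_cell_assays",
    "pcna_presets",
    "usp1_presets",
    "load_truth_config",
    "dump_truth_config",
]

TRUTH_CATEGORIES = ("ACCURATE", "TARGETED", "SEMI_TARGETED", "MIXED", "DEL1", "NON_TLS")

#: classification category each emitted truth category must map back to
EXPECTED_CLASSIFICATION = {
    "ACCURATE": "ACCURATE",
    "TARGETED": "TARGETED",
    "SEMI_TARGETED": "SEMI_TARGETED",
    "MIXED": "MIXED",
    "DEL1": "TARGETED",
    "NON_TLS": "NON_TLS",
}


@dataclass
class ConditionTruth:
    """Ground-truth parameters for one simulated condition."""

    construct_id: str
    p_repair_lesion: float
    spectrum: dict[str, float]
    p_repair_control: float = 0.8
    n_clones: int = 50
    replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("p_repair_lesion", "p_repair_control"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        unknown = set(self.spectrum) - set(TRUTH_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown spectrum categories: {sorted(unknown)}")
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum sums to {total}, not 1")
        if any(v < 0 for v in self.spectrum.values()):
            raise ValueError("negative spectrum probability")
        if self.replicates < 1 or self.n_clones < 0:
            raise ValueError("replicates must be >=1 and n_clones >=0")

    @property
    def fraction_tls(self) -> float:
        return 1.0 - self.spectrum.get("NON_TLS", 0.0)

    @property
    def true_tls_extent(self) -> float:
        """Percent of plasmids repaired by TLS under the ground truth."""
        return 100.0 * self.p_repair_lesion * self.fraction_tls

    @property
    def true_mutagenic_pct(self) -> float:
        tls = self.fraction_tls
        if tls == 0:
            raise ValueError("no TLS in spectrum")
        acc = self.spectrum.get("ACCURATE", 0.0)
        return 100.0 * (tls - acc) / tls


@dataclass
class GroundTruthConfig:
    """Full simulation configuration: constructs, conditions, seed."""

    conditions: dict[str, ConditionTruth]
    seed: int
    n_effective: int = 1000
    non_tls_del_range: tuple[int, int] = (10, 50)
    constructs: list[LesionConstruct] = field(default_factory=default_constructs)

    def __post_init__(self) -> None:
        if self.n_effective <= 0:
            raise ValueError("n_effective must be positive")
        lo, hi = self.non_tls_del_range
        if not 2 <= lo <= hi:
            raise ValueError("non_tls_del_range must satisfy 2 <= lo <= hi")
        ids = {c.id for c in self.constructs}
        for cond, truth in self.conditions.items():
            if truth.construct_id not in ids:
                raise ValueError(f"{cond}: unknown construct {truth.construct_id}")

    def construct_for(self, condition_id: str) -> LesionConstruct:
        cid = self.conditions[condition_id].construct_id
        return next(c for c in self.constructs if c.id == cid)


def _stream(seed: int, condition_id: str, replicate: int, purpose: str) -> np.random.Generator:
    """Independent, reproducible RNG keyed by (seed, condition, replicate, purpose)."""
    key = [
        seed,
        zlib.crc32(condition_id.encode()),
        replicate,
        zlib.crc32(purpose.encode()),
    ]
    return np.random.default_rng(key)


def _other_bases(base: str) -> str:
    return "ACGT".replace(base, "")


def _emit_read(
    category: str,
    construct: LesionConstruct,
    rng: np.random.Generator,
    del_range: tuple[int, int],
) -> str:
    """Apply category-specific edits to the construct reference."""
    ref = construct.reference
    ws = construct.window_start
    opp = list(construct.opposite_positions)
    flank = list(construct.flank_positions)

    def substitute(seq: list[str], pos: int) -> None:
        seq[pos] = rng.choice(list(_other_bases(seq[pos])))

    seq = list(ref)
    if category == "ACCURATE":
        pass
    elif category == "TARGETED":
        substitute(seq, int(rng.choice(opp)))
    elif category == "SEMI_TARGETED":
        substitute(seq, int(rng.choice(flank)))
    elif category == "MIXED":
        substitute(seq, int(rng.choice(opp)))
        substitute(seq, int(rng.choice(flank)))
    elif category == "DEL1":
        del seq[int(rng.choice(opp))]
    elif category == "NON_TLS":
        lo, hi = del_range
        length = int(rng.integers(lo, hi + 1))
        # deletion must overlap the window but keep >=2 nt on each read end
        start_lo = max(2, ws + 4 - length)
        start_hi = min(ws, len(ref) - length - 2)
        start = int(rng.integers(start_lo, start_hi + 1))
        del seq[start : start + length]
    else:
        raise ValueError(f"unknown truth category {category!r}")
    return "".join(seq)


@dataclass
class SimulatedCondition:
    """Output of :func:`simulate_condition` for one condition."""

    condition_id: str
    counts: list[ConditionCounts]
    reads: list[CloneRead]
    truth: dict


def simulate_condition(cfg: GroundTruthConfig, condition_id: str) -> SimulatedCondition:
    """Simulate colony counts and clone reads for one condition.

    Byte-identical for identical (config, seed); clones are allocated as
    evenly as possible across replicates.
    """
    truth = cfg.conditions[condition_id]
    construct = cfg.construct_for(condition_id)
    probs = np.array([truth.spectrum.get(c, 0.0) for c in TRUTH_CATEGORIES])

    counts: list[ConditionCounts] = []
    reads: list[CloneRead] = []
    clone_truth: dict[str, str] = {}
    base, extra = divmod(truth.n_clones, truth.replicates)
    for r in range(truth.replicates):
        rep_id = f"rep{r + 1}"
        crng = _stream(cfg.seed, condition_id, r, "counts")
        kanr = int(crng.poisson(cfg.n_effective * truth.p_repair_lesion))
        cmr = int(crng.poisson(cfg.n_effective * truth.p_repair_control))
        counts.append(ConditionCounts(condition_id, rep_id, kanr, cmr))

        n_rep = base + (1 if r < extra else 0)
        srng = _stream(cfg.seed, condition_id, r, "clones")
        cats = srng.choice(len(TRUTH_CATEGORIES), size=n_rep, p=probs)
        for j, ci in enumerate(cats):
            category = TRUTH_CATEGORIES[int(ci)]
            clone_id = f"{condition_id}_{rep_id}_c{j + 1:04d}"
            seq = _emit_read(category, construct, srng, cfg.non_tls_del_range)
            reads.append(CloneRead(clone_id, condition_id, rep_id, seq))
            clone_truth[clone_id] = category

    record = {
        "condition_id": condition_id,
        "construct_id": truth.construct_id,
        "p_repair_lesion": truth.p_repair_lesion,
        "p_repair_control": truth.p_repair_control,
        "spectrum": {c: truth.spectrum.get(c, 0.0) for c in TRUTH_CATEGORIES},
        "true_tls_extent": truth.true_tls_extent,
        "true_mutagenic_pct": truth.true_mutagenic_pct if truth.fraction_tls else None,
        "n_effective": cfg.n_effective,
        "seed": cfg.seed,
        "clone_categories": clone_truth,
    }
    return SimulatedCondition(condition_id, counts, reads, record)


def simulate_study(cfg: GroundTruthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate every condition and write FASTA + manifest + counts + truth.

    Returns the paths written: ``reads.fasta``, ``manifest.tsv``,
    ``counts.tsv``, ``truth.json``, ``constructs.json``.
    """
    from . import io as tio
    from .constructs import dump_constructs

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_counts, manifest_rows, fasta_records, truth = [], [], [], {}
    for condition_id in sorted(cfg.conditions):
        sim = simulate_condition(cfg, condition_id)
        truth[condition_id] = sim.truth
        for c in sim.counts:
            all_counts.append(
                {"condition_id": c.condition_id, "replicate_id": c.replicate_id,
                 "kanR": c.kanR, "cmR": c.cmR}
            )
        for r in sim.reads:
            fasta_records.append((r.clone_id, r.sequence))
            manifest_rows.append(
                {"clone_id": r.clone_id, "condition_id": r.condition_id,
                 "replicate_id": r.replicate_id,
                 "construct_id": cfg.conditions[condition_id].construct_id}
            )
    paths = {
        "fasta": out / "reads.fasta",
        "manifest": out / "manifest.tsv",
        "counts": out / "counts.tsv",
        "truth": out / "truth.json",
        "constructs": out / "constructs.json",
    }
    tio.write_fasta(fasta_records, paths["fasta"])
    tio.write_tsv(pd.DataFrame(manifest_rows), paths["manifest"])
    tio.write_tsv(pd.DataFrame(all_counts), paths["counts"])
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    dump_constructs(cfg.constructs, paths["constructs"])
    return paths


# -- cell-level assays ---------------------------------------------------


def simulate_cell_assays(
    foci_params: dict[str, dict[float, tuple[float, float]]],
    survival_params: dict[str, dict[float, float]],
    seed: int,
    n_cells: int = 200,
    replicates: int = 3,
    n_plated: int = 200,
    plating_efficiency: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate focus-count and colony-survival tables.

    ``foci_params[condition][timepoint] = (p_positive, mean_extra_foci)``;
    per cell the focus count is zero-inflated Poisson: 0 with probability
    1 - p_positive, else 1 + Poisson(mean_extra_foci).
    ``survival_params[condition][dose] = survival_fraction``; colony counts
    on mock and UV plates are Poisson around the plated expectation.
    """
    foci_rows = []
    for cond in sorted(foci_params):
        for t in sorted(foci_params[cond]):
            p_pos, mu = foci_params[cond][t]
            if not 0.0 <= p_pos <= 1.0 or mu < 0:
                raise ValueError(f"invalid foci parameters for {cond} at {t} h")
            for r in range(replicates):
                rng = _stream(seed, f"foci:{cond}:{t}", r, "cells")
                positive = rng.random(n_cells) < p_pos
                extras = rng.poisson(mu, size=n_cells)
                counts = np.where(positive, 1 + extras, 0)
                for i, c in enumerate(counts):
                    foci_rows.append(
                        {"cell_id": f"{cond}_t{t}_r{r + 1}_{i + 1}",
                         "condition_id": cond, "timepoint": t,
                         "experiment_id": f"exp{r + 1}", "focus_count": int(c)}
                    )
    surv_rows = []
    for cond in sorted(survival_params):
        for dose in sorted(survival_params[cond]):
            s = survival_params[cond][dose]
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"invalid survival fraction for {cond} at {dose} J/m2")
            for r in range(replicates):
                rng = _stream(seed, f"surv:{cond}:{dose}", r, "plates")
                mock = int(rng.poisson(n_plated * plating_efficiency))
                uv = int(rng.poisson(n_plated * plating_efficiency * s))
                surv_rows.append(
                    {"condition_id": cond, "dose": dose, "replicate_id": f"rep{r + 1}",
                     "colonies_uv": uv, "colonies_mock": mock}
                )
    return pd.DataFrame(foci_rows), pd.DataFrame(surv_rows)


# -- presets -------------------------------------------------------------
#
# Ground-truth presets shaped like the published headline results: three
# lesions assayed in PCNA-ubiquitination-proficient vs K164R cells (TLS
# reduced 4.4-, 3.3- and 2.6-fold; TT CPD ~98% accurate in both; TT 6-4 PP
# 64% vs 35% errors; cisPt-GG 12% vs 25% errors), and Usp1-null cells
# (TT CPD 2.3-fold and cisPt-GG 3.8-fold higher TLS).  Repair extents and
# clone numbers are assumptions (the underlying count tables are not
# machine-readable); editable like any other config.


def _spectrum(acc, targ, semi, mixed, del1, non_tls) -> dict[str, float]:
    return {
        "ACCURATE": acc, "TARGETED": targ, "SEMI_TARGETED": semi,
        "MIXED": mixed, "DEL1": del1, "NON_TLS": non_tls,
    }


def pcna_presets(seed: int, n_clones: int = 50, replicates: int = 3,
                 n_effective: int = 1000) -> GroundTruthConfig:
    """Three lesions in PCNA-ubiquitination wild-type vs K164R cells."""
    conditions = {
        # TT CPD: 98% accurate TLS in both; extent 4.4-fold lower in K164R
        "TT_CPD_wt": ConditionTruth("TT_CPD", 0.50, _spectrum(0.931, 0.0095, 0.0048, 0.0, 0.0047, 0.05)),
        "TT_CPD_k164r": ConditionTruth("TT_CPD", 0.50 / 4.4, _spectrum(0.931, 0.0095, 0.0048, 0.0, 0.0047, 0.05)),
        # TT 6-4 PP: 64% vs 35% mutagenic; extent 3.3-fold lower in K164R
        "TT_64PP_wt": ConditionTruth("TT_64PP", 0.30, _spectrum(0.342, 0.38, 0.10, 0.095, 0.033, 0.05)),
        "TT_64PP_k164r": ConditionTruth("TT_64PP", 0.30 / 3.3, _spectrum(0.6175, 0.20, 0.07, 0.04, 0.0225, 0.05)),
        # cisPt-GG: 12% vs 25% mutagenic; extent 2.6-fold lower in K164R
        "CISPT_GG_wt": ConditionTruth("CISPT_GG", 0.40, _spectrum(0.836, 0.07, 0.02, 0.012, 0.012, 0.05)),
        "CISPT_GG_k164r": ConditionTruth("CISPT_GG", 0.40 / 2.6, _spectrum(0.7125, 0.15, 0.05, 0.0225, 0.015, 0.05)),
    }
    for t in conditions.values():
        t.n_clones = n_clones
        t.replicates = replicates
    return GroundTruthConfig(conditions=conditions, seed=seed, n_effective=n_effective)


def usp1_presets(seed: int, n_clones: int = 50, replicates: int = 3,
                 n_effective: int = 1000) -> GroundTruthConfig:
    """TT CPD and cisPt-GG in Usp1 wild-type vs knockout cells."""
    cpd = _spectrum(0.931, 0.0095, 0.0048, 0.0, 0.0047, 0.05)
    gg = _spectrum(0.836, 0.07, 0.02, 0.012, 0.012, 0.05)
    conditions = {
        "TT_CPD_usp1wt": ConditionTruth("TT_CPD", 0.30, cpd),
        "TT_CPD_usp1ko": ConditionTruth("TT_CPD", 0.30 * 2.3, cpd),
        "CISPT_GG_usp1wt": ConditionTruth("CISPT_GG", 0.20, gg),
        "CISPT_GG_usp1ko": ConditionTruth("CISPT_GG", 0.20 * 3.8, gg),
    }
    for t in conditions.values():
        t.n_clones = n_clones
        t.replicates = replicates
    return GroundTruthConfig(conditions=conditions, seed=seed, n_effective=n_effective)


# -- truth-config (de)serialization --------------------------------------


def dump_truth_config(cfg: GroundTruthConfig, path: str | Path) -> None:
    payload = {
        "seed": cfg.seed,
        "n_effective": cfg.n_effective,
        "non_tls_del_range": list(cfg.non_tls_del_range),
        "constructs": [c.to_dict() for c in cfg.constructs],
        "conditions": {k: asdict(v) for k, v in cfg.conditions.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_truth_config(path: str | Path) -> GroundTruthConfig:
    data = json.loads(Path(path).read_text())
    if "seed" not in data:
        raise ValueError(f"{path}: truth config must declare a seed")
    constructs = [LesionConstruct(**c) for c in data.get("constructs", [])]
    if not constructs:
        constructs = default_constructs()
    conditions = {k: ConditionTruth(**v) for k, v in data["conditions"].items()}
    return GroundTruthConfig(
        conditions=conditions,
        seed=int(data["seed"]),
        n_effective=int(data.get("n_effective", 1000)),
        non_tls_del_range=tuple(data.get("non_tls_del_range", (10, 50))),
        constructs=constructs,
    )
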