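"""Temporal expression-screen filters and a synthetic table generator.

The screens operate on per-gene summary tables of an embryonic-stem-cell
differentiation time course (time points 0, 1, 2, 3.5, 4.5, 5.5 and 6.5
days in differentiation conditions, DDC) with FPKM expression levels,
pairwise log2 fold-changes and p-values, plus a SAG-versus-cyclopamine
(CyC) contrast at 3.5 DDC probing Shh-pathway dependence. Fold changes and
p-values are *inputs* (produced upstream by a differential-expression
pipeline); the filters implement only the bespoke selection logic:

* **down-regulated screen** — protein-coding genes expressed at 3.5 DDC
  (FPKM ≥ 2) that drop significantly between 3.5 and 5.5 DDC
  (p ≤ 0.05, log2FC ≥ cutoff, default 0.22);
* **biphasic screen** — protein-coding genes whose expression peaks at 2 or
  3.5 DDC and is repressed by CyC at 3.5 DDC, encoded as the conjunction of
  the printed fold-change/p-value inequalities.

Sign convention: log2FC of contrast "a_vs_b" is positive when expression is
higher at the first-named time point, so "down-regulated between 3.5 and
5.5 DDC" corresponds to log2fc_3p5_vs_5p5 ≥ cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TIME_POINTS",
    "REQUIRED_DOWNREG_COLUMNS",
    "REQUIRED_BIPHASIC_COLUMNS",
    "filter_downregulated",
    "classify_biphasic",
    "generate_synthetic_table",
    "read_table",
    "write_table",
]

TIME_POINTS = ("0", "1", "2", "3p5", "4p5", "5p5", "6p5")
FPKM_COLUMNS = tuple(f"fpkm_{t}" for t in TIME_POINTS)

REQUIRED_DOWNREG_COLUMNS = (
    "gene_id", "biotype", "fpkm_3p5", "log2fc_3p5_vs_5p5", "p_3p5_vs_5p5",
)

_BIPHASIC_CONTRASTS = (
    "sag_vs_cyc_3p5",
    "2_vs_0", "2_vs_1", "2_vs_4p5", "2_vs_5p5", "2_vs_6p5",
    "3p5_vs_0", "3p5_vs_1", "3p5_vs_5p5", "3p5_vs_6p5",
)
REQUIRED_BIPHASIC_COLUMNS = (
    ("gene_id", "biotype", "fpkm_2", "fpkm_3p5")
    + tuple(f"log2fc_{c}" for c in _BIPHASIC_CONTRASTS)
    + ("p_sag_vs_cyc_3p5", "p_2_vs_0", "p_2_vs_6p5", "p_3p5_vs_0", "p_3p5_vs_6p5")
)


def _require(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"expression table is missing required columns: {', '.join(missing)}")


def filter_downregulated(table: pd.DataFrame, fc_cutoff: float = 0.22) -> pd.DataFrame:
    """Boolean screen for genes down-regulated between 3.5 and 5.5 DDC.

    Returns a copy of the table with a ``downregulated_pass`` column; a gene
    passes iff FPKM(3.5) ≥ 2, p(3.5 vs 5.5) ≤ 0.05, log2FC(3.5 vs 5.5) ≥
    ``fc_cutoff`` and it is protein-coding. The default cutoff 0.22 is the
    permissive tier; 2.5 selects the strongly down-regulated tier.
    """
    if fc_cutoff < 0:
        raise ValueError("fc_cutoff must be >= 0")
    _require(table, REQUIRED_DOWNREG_COLUMNS)
    out = table.copy()
    out["downregulated_pass"] = (
        (table["fpkm_3p5"] >= 2.0)
        & (table["p_3p5_vs_5p5"] <= 0.05)
        & (table["log2fc_3p5_vs_5p5"] >= fc_cutoff)
        & (table["biotype"] == "protein_coding")
    )
    return out


def classify_biphasic(table: pd.DataFrame) -> pd.DataFrame:
    """Biphasic-gene classifier with the CyC-sensitivity gate.

    Adds boolean ``biphasic_peak2`` / ``biphasic_peak3p5`` columns and a
    ``biphasic_label`` in {"peak2", "peak3.5", "none"}. The gate requires
    expression (FPKM ≥ 2 at 2 or 3.5 DDC), CyC repression at 3.5 DDC
    (p ≤ 0.05, log2FC(SAG vs CyC) ≥ 0.5) and protein-coding biotype; the two
    peak rules are conjunctions of the per-contrast inequalities, including
    the shared log2FC(2 vs 1) ≥ 0 up-phase condition. If a gene satisfies
    both peak rules it is assigned the time point with the higher FPKM.
    """
    _require(table, REQUIRED_BIPHASIC_COLUMNS)
    t = table
    gate = (
        ((t["fpkm_2"] >= 2.0) | (t["fpkm_3p5"] >= 2.0))
        & (t["p_sag_vs_cyc_3p5"] <= 0.05)
        & (t["log2fc_sag_vs_cyc_3p5"] >= 0.5)
        & (t["biotype"] == "protein_coding")
    )
    peak2 = (
        gate
        & (t["p_2_vs_0"] <= 0.05)
        & (t["p_2_vs_6p5"] <= 0.05)
        & (t["log2fc_2_vs_0"] >= 0.5)
        & (t["log2fc_2_vs_1"] >= 0.0)
        & (t["log2fc_2_vs_6p5"] >= 0.5)
        & (t["log2fc_2_vs_5p5"] >= 0.5)
        & (t["log2fc_2_vs_4p5"] >= 0.0)
    )
    peak3p5 = (
        gate
        & (t["p_3p5_vs_0"] <= 0.05)
        & (t["p_3p5_vs_6p5"] <= 0.05)
        & (t["log2fc_3p5_vs_0"] >= 0.5)
        & (t["log2fc_3p5_vs_1"] >= 0.0)
        & (t["log2fc_2_vs_1"] >= 0.0)
        & (t["log2fc_3p5_vs_6p5"] >= 0.5)
        & (t["log2fc_3p5_vs_5p5"] >= 0.5)
    )
    out = table.copy()
    out["biphasic_peak2"] = peak2
    out["biphasic_peak3p5"] = peak3p5
    both = peak2 & peak3p5
    label = np.where(peak2, "peak2", np.where(peak3p5, "peak3.5", "none"))
    # a gene gets a single peak time: break ties by the higher expression
    label = np.where(both & (t["fpkm_3p5"] > t["fpkm_2"]), "peak3.5", label)
    out["biphasic_label"] = label
    return out


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

# log2-FPKM templates over (0, 1, 2, 3.5, 4.5, 5.5, 6.5) DDC; biphasic
# templates satisfy every inequality of exactly one peak rule with >=0.3
# log2 margin, decoys violate exactly one printed rule.
_TEMPLATES: Dict[str, np.ndarray] = {
    "biphasic_peak2":    np.array([2.0, 2.6, 4.0, 2.3, 2.2, 1.6, 1.0]),
    "biphasic_peak3p5":  np.array([2.0, 2.5, 3.0, 4.0, 3.5, 2.8, 1.8]),
    "monotone_down":     np.array([4.0, 3.6, 3.2, 2.8, 2.4, 2.0, 1.6]),
    "monotone_up":       np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]),
    "flat":              np.array([3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0]),
    "non_coding_decoy":  np.array([2.0, 2.6, 4.0, 2.3, 2.2, 1.6, 1.0]),
    "cyc_insensitive_decoy": np.array([2.0, 2.6, 4.0, 2.3, 2.2, 1.6, 1.0]),
}
# SAG-vs-CyC log2FC at 3.5 DDC per class (>= 0.5 means CyC-repressed)
_CYC_FC: Dict[str, float] = {
    "biphasic_peak2": 1.0,
    "biphasic_peak3p5": 1.2,
    "monotone_down": 0.8,
    "monotone_up": 0.0,
    "flat": 0.0,
    "non_coding_decoy": 1.0,
    "cyc_insensitive_decoy": 0.3,  # fails only the >= 0.5 CyC gate
}
_BIOTYPE: Dict[str, str] = {name: "protein_coding" for name in _TEMPLATES}
_BIOTYPE["non_coding_decoy"] = "lincRNA"  # fails only the biotype rule

_CONTRAST_PAIRS = {
    "3p5_vs_5p5": ("3p5", "5p5"),
    "2_vs_0": ("2", "0"),
    "2_vs_1": ("2", "1"),
    "2_vs_4p5": ("2", "4p5"),
    "2_vs_5p5": ("2", "5p5"),
    "2_vs_6p5": ("2", "6p5"),
    "3p5_vs_0": ("3p5", "0"),
    "3p5_vs_1": ("3p5", "1"),
    "3p5_vs_6p5": ("3p5", "6p5"),
}

TRUE_CLASSES = tuple(_TEMPLATES)


def generate_synthetic_table(
    n_genes: int,
    class_mix: Optional[Dict[str, float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-gene summary table with planted ground-truth labels.

    Each gene is drawn from a class template: log2-FPKM time courses get
    i.i.d. normal noise of ``noise_sd`` (log2 units), log2 fold-changes are
    the noiseless template contrasts plus the same noise, and p-values are
    small (1e-4) for contrasts with a true template change (|log2FC| ≥ 0.25)
    and drawn uniformly from (0.1, 1) otherwise. Ground truth is emitted in
    a ``true_class`` column. Decoy classes violate exactly one screen rule
    (biotype, or the CyC fold-change gate).
    """
    class_mix = class_mix or {name: 1.0 / len(TRUE_CLASSES) for name in TRUE_CLASSES}
    unknown = set(class_mix) - set(TRUE_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes in class_mix: {sorted(unknown)}")
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class_mix fractions must sum to 1, got {total}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    # largest-remainder apportionment of n_genes across classes
    names = list(class_mix)
    raw = np.array([class_mix[c] * n_genes for c in names])
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n_genes - counts.sum()]:
        counts[i] += 1

    rng = np.random.default_rng(seed)
    records = []
    g = 0
    for cls, count in zip(names, counts):
        template = _TEMPLATES[cls]
        for _ in range(count):
            log2_fpkm = template + rng.normal(0.0, noise_sd, size=template.size)
            rec = {"gene_id": f"gene_{g:05d}", "biotype": _BIOTYPE[cls],
                   "true_class": cls}
            for tp, v in zip(TIME_POINTS, log2_fpkm):
                rec[f"fpkm_{tp}"] = float(2.0**v)
            for contrast, (a, b) in _CONTRAST_PAIRS.items():
                ia, ib = TIME_POINTS.index(a), TIME_POINTS.index(b)
                true_fc = template[ia] - template[ib]
                rec[f"log2fc_{contrast}"] = float(
                    true_fc + rng.normal(0.0, noise_sd) if noise_sd > 0 else true_fc
                )
                if f"p_{contrast}" in _P_COLUMNS:
                    rec[f"p_{contrast}"] = (
                        1e-4 if abs(true_fc) >= 0.25 else float(rng.uniform(0.1, 1.0))
                    )
            cyc_fc = _CYC_FC[cls]
            rec["log2fc_sag_vs_cyc_3p5"] = float(
                cyc_fc + rng.normal(0.0, noise_sd) if noise_sd > 0 else cyc_fc
            )
            rec["p_sag_vs_cyc_3p5"] = (
                1e-4 if abs(cyc_fc) >= 0.25 else float(rng.uniform(0.1, 1.0))
            )
            records.append(rec)
            g += 1
    return pd.DataFrame.from_records(records)


_P_COLUMNS = {"p_3p5_vs_5p5", "p_2_vs_0", "p_2_vs_6p5", "p_3p5_vs_0", "p_3p5_vs_6p5"}


def read_table(path) -> pd.DataFrame:
    """Read an expression table from TSV (or CSV if the suffix is .csv)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def write_table(table: pd.DataFrame, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    table.to_csv(path, sep=sep, index=False)
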