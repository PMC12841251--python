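"""Taste activity values, taste-category aggregates and equivalent umami concentration.

Scores free-amino-acid (FAA) and 5'-nucleotide panels measured in crustacean
tissue (mg per 100 g). Three quantities are computed:

* **TAV** (taste activity value): concentration divided by the compound's
  sensory detection threshold. TAV >= 1 marks a perceptible contributor.
* **Category aggregates**: per-group sums of umami (UAA), sweet (SAA),
  bitter (BAA), essential (EAA) and total (TAA) free amino acids, plus the
  total flavor-nucleotide pool.
* **EUC** (equivalent umami concentration): grams of monosodium-glutamate
  equivalent per 100 g from the Yamaguchi synergy model

      EUC = sum(a_i * b_i) + 1218 * sum(a_i * b_i) * sum(a_j * b_j)

  where ``a_i, b_i`` are umami amino-acid concentrations (g/100 g) and
  relative coefficients (Glu 1, Asp 0.077) and ``a_j, b_j`` the nucleotide
  ones (IMP 1, GMP 2.3, AMP 0.18).

Concentrations are in mg/100 g tissue while thresholds are tabulated in
mg/100 mL; the two are treated as directly comparable (tissue density ~1),
which is the convention the field's printed TAV tables follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SYNERGY_CONSTANT",
    "UMAMI_AMINO_ACIDS",
    "UMAMI_NUCLEOTIDES",
    "EucResult",
    "MissingThresholdError",
    "load_reference",
    "load_panel_summary",
    "compute_tav",
    "tav_table",
    "aggregate_categories",
    "replicate_category_sums",
    "compute_euc",
    "euc_by_group",
]

#: Multiplicative constant of the Yamaguchi umami synergy model.
SYNERGY_CONSTANT = 1218.0

#: Compounds entering the amino-acid term of the EUC model.
UMAMI_AMINO_ACIDS = ("Glu", "Asp")

#: Compounds entering the nucleotide term of the EUC model.
UMAMI_NUCLEOTIDES = ("IMP", "GMP", "AMP")

_CATEGORY_OF_ATTRIBUTE = {"umami": "UAA", "sweet": "SAA", "bitter": "BAA"}


class MissingThresholdError(KeyError):
    """Raised when a TAV is requested for a compound with no sensory threshold."""


@dataclass(frozen=True)
class EucResult:
    """EUC for one sample or group, with its two terms kept for auditing.

    ``euc = amino_term + 1218 * amino_term * nucleotide_term``; all three
    values are in g MSG-equivalent (or g compound) per 100 g tissue.
    """

    group: str
    euc: float
    amino_term: float
    nucleotide_term: float


def _data_path(name: str):
    return resources.files("savor.data").joinpath(name)


def load_reference(path=None) -> pd.DataFrame:
    """Load a taste reference table (default: the packaged one).

    Columns: ``compound, compound_class, taste_attribute, threshold,
    umami_coefficient, is_essential``. Thresholds are mg/100 mL; absent
    thresholds (no TAV defined for the compound) are NaN.
    """
    src = _data_path("taste_reference.csv") if path is None else path
    with resources.as_file(src) if path is None else _nullcontext(src) as p:
        ref = pd.read_csv(p)
    required = {
        "compound",
        "compound_class",
        "taste_attribute",
        "threshold",
        "umami_coefficient",
        "is_essential",
    }
    missing = required - set(ref.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    ref["is_essential"] = ref["is_essential"].astype(bool)
    if (ref["threshold"].dropna() <= 0).any():
        raise ValueError("thresholds must be positive")
    if ref["compound"].duplicated().any():
        dupes = ref.loc[ref["compound"].duplicated(), "compound"].tolist()
        raise ValueError(f"duplicate compounds in reference: {dupes}")
    return ref.set_index("compound", drop=False)


class _nullcontext:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def load_panel_summary() -> pd.DataFrame:
    """Packaged mean +/- SD grid: 20 FAAs + 3 nucleotides x 3 storage groups.

    Long format with columns ``compound, group, mean, sd`` (mg/100 g, n = 6
    animals per group). Groups: CK48 (ambient seawater control), ICE48
    (ice-chilled) and LTA48 (low-temperature acidified seawater), all 48 h
    post-molting.
    """
    with resources.as_file(_data_path("panel_summary.csv")) as p:
        return pd.read_csv(p)


def compute_tav(concentration: float, threshold: float) -> float:
    """Taste activity value: concentration / sensory threshold.

    Parameters
    ----------
    concentration
        Compound concentration, mg/100 g tissue; must be >= 0.
    threshold
        Sensory detection threshold, mg/100 mL; must be > 0.
    """
    if threshold is None or not np.isfinite(threshold):
        raise MissingThresholdError("no threshold supplied")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if concentration < 0:
        raise ValueError(f"concentration must be non-negative, got {concentration}")
    return concentration / threshold


def _group_means(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long concentration table to one mean per (compound, group)."""
    _check_records(records)
    if "replicate" in records.columns:
        return (
            records.groupby(["compound", "group"], sort=False)["concentration"]
            .mean()
            .reset_index()
        )
    return records[["compound", "group", "concentration"]].copy()


def _check_records(records: pd.DataFrame) -> None:
    required = {"compound", "group", "concentration"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    if (records["concentration"] < 0).any():
        bad = records.loc[records["concentration"] < 0, "compound"].tolist()
        raise ValueError(f"negative concentrations for: {bad}")
    if "replicate" in records.columns:
        key = records[["compound", "group", "replicate"]]
        if key.duplicated().any():
            raise ValueError("(compound, group, replicate) must be unique")


def tav_table(
    records: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """TAVs for every (compound, group) in a concentration table.

    By default TAVs are computed on group-mean concentrations, matching how
    published tables report them; ``per_replicate=True`` scores each animal
    instead. Compounds without a threshold in the reference are an error —
    never silently scored as zero.

    Returns a tidy frame ``compound, group, tav, concentration_used,
    threshold_used`` (plus ``replicate`` in per-replicate mode).
    """
    if reference is None:
        reference = load_reference()
    if per_replicate:
        base = records.copy()
        _check_records(base)
    else:
        base = _group_means(records)

    unknown = sorted(set(base["compound"]) - set(reference.index))
    if unknown:
        raise KeyError(f"compounds absent from reference: {unknown}")
    thresholds = reference.loc[base["compound"], "threshold"].to_numpy()
    no_thr = base.loc[np.isnan(thresholds), "compound"].unique().tolist()
    if no_thr:
        raise MissingThresholdError(
            f"no sensory threshold for requested compounds: {no_thr}"
        )
    out = base.rename(columns={"concentration": "concentration_used"})
    out["threshold_used"] = thresholds
    out["tav"] = out["concentration_used"] / out["threshold_used"]
    cols = ["compound", "group"]
    if per_replicate:
        cols.append("replicate")
    return out[cols + ["tav", "concentration_used", "threshold_used"]]


def _category_sums(conc: pd.DataFrame, reference: pd.DataFrame) -> dict[str, float]:
    """Category totals for one group (or one replicate) of concentrations."""
    ref = reference.loc[conc["compound"]]
    c = conc["concentration"].to_numpy()
    is_faa = (ref["compound_class"] == "FAA").to_numpy()
    out = {}
    for attr, cat in _CATEGORY_OF_ATTRIBUTE.items():
        out[cat] = float(c[is_faa & (ref["taste_attribute"] == attr).to_numpy()].sum())
    out["EAA"] = float(c[is_faa & ref["is_essential"].to_numpy()].sum())
    out["TAA"] = float(c[is_faa].sum())
    out["total_nucleotide"] = float(c[~is_faa].sum())
    return out


def aggregate_categories(
    records: pd.DataFrame, reference: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-group taste-category totals (sums of group-mean concentrations).

    Categories: UAA (umami FAAs), SAA (sweet), BAA (bitter), EAA (essential),
    TAA (all FAAs including tasteless) and total_nucleotide. Totals are sums
    of per-compound group means — not means of per-animal sums — so they
    reproduce the layout of published composition tables. Use
    :func:`replicate_category_sums` for per-animal totals (e.g. to attach
    SDs to the aggregates).

    Returns a tidy frame ``group, category, value`` (mg/100 g).
    """
    if reference is None:
        reference = load_reference()
    means = _group_means(records)
    unknown = sorted(set(means["compound"]) - set(reference.index))
    if unknown:
        raise KeyError(f"compounds absent from reference: {unknown}")
    rows = []
    for group, sub in means.groupby("group", sort=False):
        for cat, value in _category_sums(sub, reference).items():
            rows.append({"group": group, "category": cat, "value": value})
    if not rows:
        return pd.DataFrame(columns=["group", "category", "value"])
    return pd.DataFrame(rows)


def replicate_category_sums(
    records: pd.DataFrame, reference: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-(group, replicate) category totals; feeds SDs of the aggregates."""
    if reference is None:
        reference = load_reference()
    _check_records(records)
    if "replicate" not in records.columns:
        raise ValueError("replicate-level records required")
    unknown = sorted(set(records["compound"]) - set(reference.index))
    if unknown:
        raise KeyError(f"compounds absent from reference: {unknown}")
    rows = []
    for (group, rep), sub in records.groupby(["group", "replicate"], sort=False):
        for cat, value in _category_sums(sub, reference).items():
            rows.append(
                {"group": group, "replicate": rep, "category": cat, "value": value}
            )
    return pd.DataFrame(rows)


def compute_euc(
    concentrations: Mapping[str, float],
    reference: pd.DataFrame | None = None,
    group: str = "",
) -> EucResult:
    """Equivalent umami concentration from a compound -> mg/100 g map.

    Inputs are mg/100 g and are converted to g/100 g before the coefficients
    are applied. Only Glu and Asp enter the amino-acid term and only IMP, GMP
    and AMP the nucleotide term; any of the five that is absent from the map
    contributes zero (a warning is emitted so partial panels are auditable).
    """
    if reference is None:
        reference = load_reference()
    coef = reference["umami_coefficient"]

    def term(compounds: Iterable[str]) -> float:
        total = 0.0
        for cmp_id in compounds:
            if cmp_id not in concentrations:
                warnings.warn(
                    f"{cmp_id} missing from EUC input; contributes 0", stacklevel=3
                )
                continue
            conc = concentrations[cmp_id]
            if conc < 0:
                raise ValueError(f"negative concentration for {cmp_id}: {conc}")
            total += (conc / 1000.0) * float(coef.loc[cmp_id])
        return total

    amino = term(UMAMI_AMINO_ACIDS)
    nucleotide = term(UMAMI_NUCLEOTIDES)
    euc = amino + SYNERGY_CONSTANT * amino * nucleotide
    return EucResult(group=group, euc=euc, amino_term=amino, nucleotide_term=nucleotide)


def euc_by_group(
    records: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    per_replicate: bool = True,
) -> pd.DataFrame:
    """EUC per group from a long concentration table.

    With replicate-level data the default scores each animal and reports the
    group mean +/- SD (``euc_sd`` is NaN when only means are available or
    ``per_replicate=False``).

    Returns ``group, euc, euc_sd, amino_term, nucleotide_term`` where the
    term columns correspond to the group-mean computation.
    """
    if reference is None:
        reference = load_reference()
    rows = []
    has_reps = per_replicate and "replicate" in records.columns
    for group, sub in records.groupby("group", sort=False):
        mean_conc = (
            sub.groupby("compound")["concentration"].mean()
            if "replicate" in sub.columns
            else sub.set_index("compound")["concentration"]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean_res = compute_euc(mean_conc.to_dict(), reference, group=group)
        if has_reps:
            per_rep = []
            for _, rep_sub in sub.groupby("replicate", sort=False):
                conc = rep_sub.set_index("compound")["concentration"].to_dict()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    per_rep.append(compute_euc(conc, reference, group=group).euc)
            euc = float(np.mean(per_rep))
            euc_sd = float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else np.nan
        else:
            euc, euc_sd = mean_res.euc, np.nan
        rows.append(
            {
                "group": group,
                "euc": euc,
                "euc_sd": euc_sd,
                "amino_term": mean_res.amino_term,
                "nucleotide_term": mean_res.nucleotide_term,
            }
        )
    return pd.DataFrame(rows)
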