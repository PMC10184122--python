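"""Per-complex aggregation of H-bond rupture free energies.

Each ternary (or binary) complex is characterized by three interface H-bonds
(W400--N39, H357--T38, N351--I37 in the CRBN--CK1α system); their endpoint
rupture PMFs are summed into a per-complex total ΣPMF (justified by the
absence of co-dependence between the ruptures), referenced against the
wild-type ternary complex, and correlated with binding free energies ΔG_bin
derived from measured K_D values.

Error propagation is *linear* (sd values add), matching the convention of the
published per-complex totals; quadrature addition is available as a flag.
Published totals that disagree with the re-added per-bond values are flagged,
never silently corrected — recomputed sums are authoritative in all outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BONDS",
    "EnergeticsTable",
    "CorrelationResult",
    "load_reference_endpoints",
    "load_reference_totals",
    "sum_pmf",
    "relative_pmf",
    "build_energetics_table",
    "correlate_with_affinity",
]

#: canonical interface H-bond labels, interface order
BONDS = ("W400-N39", "H357-T38", "N351-I37")

_COLUMNS = ("complex", "bond", "pmf_kcal_mol", "sd_kcal_mol")


def load_reference_endpoints() -> pd.DataFrame:
    """Published per-bond PMF endpoints for the six CRBN--CK1α complexes."""
    with resources.files("glueforce.data").joinpath("published_endpoints.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_reference_totals() -> pd.DataFrame:
    """Published per-complex ΣPMF values as printed (three disagree with the
    re-added per-bond sums; see :func:`build_energetics_table`)."""
    with resources.files("glueforce.data").joinpath("published_totals.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    if records.duplicated(["complex", "bond"]).any():
        raise ValueError("(complex, bond) pairs must be unique")
    if (records["sd_kcal_mol"] < 0).any():
        raise ValueError("sd values must be >= 0")
    return records


def sum_pmf(
    records: pd.DataFrame,
    bonds: tuple[str, ...] = BONDS,
    quadrature: bool = False,
) -> tuple[float, float]:
    """Total rupture PMF of one complex: Σ endpoints with propagated error.

    ``records`` holds the rows of a single complex; all ``bonds`` must be
    present.  The error is the linear sum of the per-bond sd values unless
    ``quadrature`` is set.
    """
    _validate_records(records)
    if records["complex"].nunique() != 1:
        raise ValueError("sum_pmf expects the records of exactly one complex")
    have = set(records["bond"])
    missing = [b for b in bonds if b not in have]
    if missing:
        raise ValueError(
            f"complex {records['complex'].iloc[0]!r} is missing bonds: {missing}"
        )
    sub = records.set_index("bond").loc[list(bonds)]
    total = float(sub["pmf_kcal_mol"].sum())
    if quadrature:
        err = float(np.sqrt((sub["sd_kcal_mol"] ** 2).sum()))
    else:
        err = float(sub["sd_kcal_mol"].sum())
    return total, err


def relative_pmf(
    value: float, sd: float, ref_value: float, ref_sd: float
) -> tuple[float, float]:
    """Difference vs the reference complex, error = sum of the two sd values."""
    if sd < 0 or ref_sd < 0:
        raise ValueError("sd values must be >= 0")
    return float(value - ref_value), float(sd + ref_sd)


@dataclass(frozen=True)
class EnergeticsTable:
    """Per-complex, per-bond energetics in the published layout.

    ``absolute``/``relative`` are bond x complex DataFrames of "value ± sd"
    pairs stored as (value, sd) column MultiIndex; ``totals`` holds the
    recomputed ΣPMF row.  ``mismatches`` lists complexes whose supplied
    printed totals differ from the recomputed sums at one decimal.
    """

    absolute: pd.DataFrame
    relative: pd.DataFrame
    totals: pd.DataFrame  # index complex; columns sum, sd, rel, rel_sd
    reference: str
    mismatches: tuple[str, ...] = ()

    def to_tidy(self) -> pd.DataFrame:
        """Long-format records (complex, bond, pmf, sd, rel, rel_sd)."""
        rows = []
        for bond in self.absolute.index:
            for cplx in self.absolute.columns.levels[0]:
                rows.append(
                    {
                        "complex": cplx,
                        "bond": bond,
                        "pmf_kcal_mol": self.absolute.loc[bond, (cplx, "value")],
                        "sd_kcal_mol": self.absolute.loc[bond, (cplx, "sd")],
                        "rel_kcal_mol": self.relative.loc[bond, (cplx, "value")],
                        "rel_sd_kcal_mol": self.relative.loc[bond, (cplx, "sd")],
                    }
                )
        return pd.DataFrame(rows)


def build_energetics_table(
    records: pd.DataFrame,
    reference: str = "wt_LEN",
    printed_totals: pd.DataFrame | None = None,
    bonds: tuple[str, ...] = BONDS,
) -> EnergeticsTable:
    """Assemble absolute, relative and ΣPMF values for a set of complexes.

    Every complex must carry the full bond set (incomplete complexes are
    listed by name).  Relative values are computed against ``reference``.  If
    ``printed_totals`` (complex, sum_pmf_kcal_mol, sd_kcal_mol) is supplied,
    recomputed sums are checked against it at one decimal and disagreements
    are surfaced both as a warning and in ``mismatches``; the recomputed
    values remain authoritative.
    """
    records = _validate_records(records)
    complexes = list(dict.fromkeys(records["complex"]))  # preserve order
    if reference not in complexes:
        raise ValueError(f"reference complex {reference!r} not in records")
    incomplete = [
        c
        for c in complexes
        if set(bonds) - set(records.loc[records["complex"] == c, "bond"])
    ]
    if incomplete:
        raise ValueError(f"incomplete complexes: {incomplete}")

    pivot_v = records.pivot(index="bond", columns="complex", values="pmf_kcal_mol")
    pivot_s = records.pivot(index="bond", columns="complex", values="sd_kcal_mol")
    pivot_v = pivot_v.loc[list(bonds), complexes]
    pivot_s = pivot_s.loc[list(bonds), complexes]

    absolute = pd.concat({"value": pivot_v, "sd": pivot_s}, axis=1)
    absolute = absolute.swaplevel(axis=1).sort_index(
        axis=1, level=0, key=lambda idx: idx.map({c: i for i, c in enumerate(complexes)})
    )

    rel_v = pivot_v.sub(pivot_v[reference], axis=0)
    rel_s = pivot_s.add(pivot_s[reference], axis=0)
    relative = pd.concat({"value": rel_v, "sd": rel_s}, axis=1)
    relative = relative.swaplevel(axis=1).sort_index(
        axis=1, level=0, key=lambda idx: idx.map({c: i for i, c in enumerate(complexes)})
    )

    totals = pd.DataFrame(
        [
            dict(
                zip(
                    ("sum_pmf_kcal_mol", "sd_kcal_mol"),
                    sum_pmf(records[records["complex"] == c], bonds=bonds),
                )
            )
            for c in complexes
        ],
        index=pd.Index(complexes, name="complex"),
    )
    ref_sum = totals.loc[reference]
    totals["rel_kcal_mol"] = totals["sum_pmf_kcal_mol"] - ref_sum["sum_pmf_kcal_mol"]
    totals["rel_sd_kcal_mol"] = totals["sd_kcal_mol"] + ref_sum["sd_kcal_mol"]

    mismatches: list[str] = []
    if printed_totals is not None:
        printed = printed_totals.set_index("complex")
        for c in complexes:
            if c not in printed.index:
                continue
            if round(totals.loc[c, "sum_pmf_kcal_mol"], 1) != round(
                float(printed.loc[c, "sum_pmf_kcal_mol"]), 1
            ):
                mismatches.append(c)
        if mismatches:
            warnings.warn(
                "printed totals differ from recomputed per-bond sums for: "
                + ", ".join(
                    f"{c} (printed {printed.loc[c, 'sum_pmf_kcal_mol']:.1f}, "
                    f"recomputed {totals.loc[c, 'sum_pmf_kcal_mol']:.1f})"
                    for c in mismatches
                )
                + "; recomputed values are used"
            )

    return EnergeticsTable(
        absolute=absolute,
        relative=relative,
        totals=totals,
        reference=reference,
        mismatches=tuple(mismatches),
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Ordinary least-squares line and squared Pearson correlation."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def correlate_with_affinity(
    totals: pd.Series, dg_bin: pd.Series
) -> CorrelationResult:
    """Correlate per-complex ΣPMF with binding free energy ΔG_bin.

    Both inputs are indexed by complex label; only labels present in both are
    used and at least three paired points are required.  Returns the OLS line
    ΔG_bin = slope * ΣPMF + intercept and R² (squared Pearson correlation).
    """
    common = totals.index.intersection(dg_bin.index)
    unpaired = totals.index.symmetric_difference(dg_bin.index)
    if len(unpaired):
        raise ValueError(f"unpaired complex labels: {sorted(map(str, unpaired))}")
    if len(common) < 3:
        raise ValueError("at least three paired points are required")
    x = totals.loc[common].to_numpy(dtype=float)
    y = dg_bin.loc[common].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(common),
    )
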