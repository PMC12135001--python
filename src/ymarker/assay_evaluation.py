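"""Confusion statistics for a sexing assay: per-cultivar counts of
correct and incorrect calls, the true positive success rate, and the
specificity.

Conventions: a sample whose PCR failed (no control band) counts in the
denominator but never in the numerator; the true positive success rate
is the fraction of samples whose genetic call matches the phenotypic
sex; specificity is the fraction of phenotypic males NOT called female —
the costly error when purging males from a crop is a male slipping
through as a female.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import math

import pandas as pd

PHENOTYPIC_SEXES = ("male", "female")
CALLED_SEXES = ("male", "female", "failed")

RESULT_COLUMNS = ["sample_id", "cultivar", "phenotypic_sex", "called_sex"]
COUNT_COLUMNS = [
    "cultivar",
    "n",
    "male_as_male",
    "female_as_female",
    "male_as_female",
    "female_as_male",
    "failed",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """Per-cultivar and total confusion counts.

    ``per_cultivar`` has the count columns plus ``tpr_percent`` (rounded
    to the nearest integer); the total rate is kept at one decimal.
    ``specificity_percent`` is ``nan`` when no phenotypic males exist.
    """

    per_cultivar: pd.DataFrame
    total: pd.Series

    @property
    def tpr_percent(self) -> float:
        return float(self.total["tpr_percent"])

    @property
    def specificity_percent(self) -> float:
        mm = int(self.total["male_as_male"])
        mf = int(self.total["male_as_female"])
        if mm + mf == 0:
            return math.nan
        return 100.0 * mm / (mm + mf)

    def to_frame(self) -> pd.DataFrame:
        total_row = self.total.copy()
        total_row["cultivar"] = "Total"
        out = pd.concat(
            [self.per_cultivar, total_row.to_frame().T], ignore_index=True
        )[COUNT_COLUMNS + ["tpr_percent"]]
        count_cols = [c for c in COUNT_COLUMNS if c != "cultivar"]
        out[count_cols] = out[count_cols].astype(int)
        return out


def _validate_results(results: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table missing columns {missing}")
    if results.empty:
        raise ValueError("results table is empty")
    if results["sample_id"].duplicated().any():
        dup = results.loc[results["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    for _, row in results.iterrows():
        if row["phenotypic_sex"] not in PHENOTYPIC_SEXES:
            raise ValueError(
                f"sample {row['sample_id']}: unknown phenotypic_sex {row['phenotypic_sex']!r}"
            )
        if row["called_sex"] not in CALLED_SEXES:
            raise ValueError(
                f"sample {row['sample_id']}: unknown called_sex {row['called_sex']!r}"
            )
    return results


def _count_block(group: pd.DataFrame) -> dict:
    pheno, called = group["phenotypic_sex"], group["called_sex"]
    return {
        "n": len(group),
        "male_as_male": int(((pheno == "male") & (called == "male")).sum()),
        "female_as_female": int(((pheno == "female") & (called == "female")).sum()),
        "male_as_female": int(((pheno == "male") & (called == "female")).sum()),
        "female_as_male": int(((pheno == "female") & (called == "male")).sum()),
        "failed": int((called == "failed").sum()),
    }


def summarize(results: pd.DataFrame) -> ConfusionSummary:
    """Collapse a per-sample results table into per-cultivar and total
    confusion counts with their true positive success rates."""
    results = _validate_results(results)
    rows = []
    for cultivar, group in results.groupby("cultivar", sort=True):
        block = _count_block(group)
        correct = block["male_as_male"] + block["female_as_female"]
        rows.append(
            {"cultivar": cultivar, **block, "tpr_percent": round(100.0 * correct / block["n"])}
        )
    per_cultivar = pd.DataFrame(rows)
    return ConfusionSummary(per_cultivar=per_cultivar, total=_total_from(per_cultivar))


def _total_from(per_cultivar: pd.DataFrame) -> pd.Series:
    count_cols = [c for c in COUNT_COLUMNS if c != "cultivar"]
    total = per_cultivar[count_cols].sum()
    correct = total["male_as_male"] + total["female_as_female"]
    total["tpr_percent"] = round(100.0 * correct / total["n"], 1)
    return total


def summarize_counts(counts: pd.DataFrame) -> ConfusionSummary:
    """Summary straight from per-cultivar count columns (no sample-level
    rows needed): recomputes the rates from the counts."""
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table missing columns {missing}")
    counts = counts[COUNT_COLUMNS].copy()
    parts = counts[
        ["male_as_male", "female_as_female", "male_as_female", "female_as_male", "failed"]
    ].sum(axis=1)
    if not (parts == counts["n"]).all():
        bad = counts.loc[parts != counts["n"], "cultivar"].iloc[0]
        raise ValueError(f"cultivar {bad!r}: counts do not sum to n")
    correct = counts["male_as_male"] + counts["female_as_female"]
    counts["tpr_percent"] = (100.0 * correct / counts["n"]).round().astype(int)
    return ConfusionSummary(per_cultivar=counts, total=_total_from(counts))


def expand_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct a per-sample results table from per-cultivar counts.

    Sample identities are synthetic; the summary statistics depend only
    on the counts, so the expansion is exact for evaluation purposes.
    """
    rows = []
    for _, r in counts.iterrows():
        combos = [
            ("male", "male", int(r["male_as_male"])),
            ("female", "female", int(r["female_as_female"])),
            ("male", "female", int(r["male_as_female"])),
            ("female", "male", int(r["female_as_male"])),
        ]
        n_failed = int(r["failed"])
        idx = 0
        for pheno, called, count in combos:
            for _ in range(count):
                rows.append(
                    {
                        "sample_id": f"{r['cultivar']}_{idx:03d}",
                        "cultivar": r["cultivar"],
                        "phenotypic_sex": pheno,
                        "called_sex": called,
                    }
                )
                idx += 1
        for _ in range(n_failed):
            # failed rows need a phenotypic sex; alternate to stay balanced
            rows.append(
                {
                    "sample_id": f"{r['cultivar']}_{idx:03d}",
                    "cultivar": r["cultivar"],
                    "phenotypic_sex": "male" if idx % 2 else "female",
                    "called_sex": "failed",
                }
            )
            idx += 1
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def compare_to_truth(calls: dict[str, str], truth: pd.DataFrame) -> pd.DataFrame:
    """Join per-sample genetic calls with phenotypic truth.

    ``truth`` needs columns sample_id / cultivar / phenotypic_sex; the
    sample_id sets must match exactly.
    """
    truth_ids = set(truth["sample_id"])
    call_ids = set(calls)
    if truth_ids != call_ids:
        only_truth = sorted(truth_ids - call_ids)[:5]
        only_calls = sorted(call_ids - truth_ids)[:5]
        raise ValueError(
            f"sample sets differ (truth-only: {only_truth}, calls-only: {only_calls})"
        )
    out = truth[["sample_id", "cultivar", "phenotypic_sex"]].copy()
    out["called_sex"] = out["sample_id"].map(calls)
    return out[RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# I/O


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return _validate_results(df)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results[RESULT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_summary(summary: ConfusionSummary, path: str | Path) -> None:
    summary.to_frame().to_csv(path, sep="\t", index=False)


def load_published_counts() -> pd.DataFrame:
    """The packaged 192-sample, 12-cultivar assay count table."""
    from importlib.resources import files

    return read_counts(files("ymarker.data") / "table2_counts.tsv")
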