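"""Qualitative expression calls from normalized TPM matrices.

Two summaries: the developmental stage at which each transcript peaks
(argmax of replicate-mean TPM) and whether a transcript is
qualitatively sex-biased between adult male and female samples.  No
differential-expression statistics are attempted — the calls mirror
heatmap-level reading of a TPM table.  "Qualitatively distinct between
the sexes" is operationalized as at least a 2-fold mean difference with
the higher mean above 1 TPM; both thresholds are configurable and
reported in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import OpsinkitError

# canonical developmental ordering used to break exact peak ties
STAGE_ORDER = ("blastula", "gastrula", "planula", "polyp",
               "adult_male", "adult_female", "adult")


@dataclass
class PeakCall:
    transcript: str
    peak_stage: str          # stage name, or "not_expressed"
    mean_tpm: float
    tied: bool = False


@dataclass
class SexBiasCall:
    transcript: str
    bias: str                # {male, female, none}
    fold_change: float       # >= 1 when bias != none


def _stage_means(matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    missing = set(matrix.columns) - set(sheet.index)
    if missing:
        raise OpsinkitError(f"samples without metadata: {sorted(missing)[:5]}")
    stages = sheet.loc[list(matrix.columns), "stage"]
    return matrix.T.groupby(stages.values).mean().T


def peak_stage(matrix: pd.DataFrame, sheet: pd.DataFrame) -> list[PeakCall]:
    """Per-transcript peak stage: argmax over stages of replicate means.

    Exact ties go to the earliest developmental stage and are flagged;
    an all-zero transcript is called ``not_expressed``.
    """
    means = _stage_means(matrix, sheet)
    order = [s for s in STAGE_ORDER if s in means.columns]
    order += [s for s in means.columns if s not in order]
    means = means[order]
    calls = []
    for t, row in means.iterrows():
        if (row == 0).all():
            calls.append(PeakCall(t, "not_expressed", 0.0))
            continue
        top = row.max()
        winners = [s for s in order if row[s] == top]
        calls.append(PeakCall(t, winners[0], float(top), tied=len(winners) > 1))
    return calls


def sex_bias_flags(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    min_fold: float = 2.0,
    min_tpm: float = 1.0,
) -> list[SexBiasCall]:
    """Flag transcripts whose adult expression differs between sexes.

    Bias is called when the higher-sex mean is at least ``min_fold``
    times the lower-sex mean and itself at least ``min_tpm``.  Calls are
    invariant under global rescaling only as far as the ``min_tpm``
    floor allows, which is why the floor is low and configurable.
    """
    male_cols = [s for s in matrix.columns if sheet.loc[s, "sex"] == "male"]
    female_cols = [s for s in matrix.columns if sheet.loc[s, "sex"] == "female"]
    if not male_cols or not female_cols:
        raise OpsinkitError("both sexes need at least one sample")
    calls = []
    for t in matrix.index:
        m = float(matrix.loc[t, male_cols].mean())
        f = float(matrix.loc[t, female_cols].mean())
        hi, lo = max(m, f), min(m, f)
        fold = hi / lo if lo > 0 else float("inf")
        if hi >= min_tpm and fold >= min_fold:
            calls.append(SexBiasCall(t, "male" if m > f else "female", fold))
        else:
            calls.append(SexBiasCall(t, "none", 1.0))
    return calls


def calls_to_frame(peaks: list[PeakCall], biases: list[SexBiasCall],
                   min_fold: float = 2.0, min_tpm: float = 1.0) -> pd.DataFrame:
    """Merge both call sets into one table (threshold note in attrs)."""
    by_t = {b.transcript: b for b in biases}
    rows = []
    for p in peaks:
        b = by_t.get(p.transcript)
        rows.append({
            "transcript": p.transcript,
            "peak_stage": p.peak_stage,
            "peak_mean_tpm": p.mean_tpm,
            "peak_tied": p.tied,
            "sex_bias": b.bias if b else "none",
            "sex_fold_change": b.fold_change if b else 1.0,
        })
    out = pd.DataFrame(rows).set_index("transcript")
    out.attrs["thresholds"] = {"min_fold": min_fold, "min_tpm": min_tpm}
    return out
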