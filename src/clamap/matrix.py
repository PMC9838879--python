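"""Assembly of per-cell metrics into the input x output x subtype matrix.

The strength matrix mirrors the published cross-tabulation: for each metric
(auc, aps, binary) and each of the 70 (input, output, subtype) combinations
it holds the contributing per-cell values together with mean, SEM (sd/sqrt n)
and n summaries. Only QC-passing cells contribute.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, LabelingError
from .regions import INPUT_REGIONS, OUTPUT_REGIONS, SUBTYPES

METRICS = ("auc", "aps", "binary")
_METRIC_COLUMNS = {"auc": "mean_auc", "aps": "mean_aps_per_pulse", "binary": "binary_response"}


class StrengthMatrix:
    """Per-cell circuit-strength values plus per-entry summaries.

    Parameters
    ----------
    cells : DataFrame
        One row per QC-passing cell with columns ``cell_id, input, output,
        subtype, mean_auc, mean_aps_per_pulse, binary_response`` (and
        optionally ``auc_0mw``, the no-light reference used for effect sizes).
    """

    def __init__(self, cells: pd.DataFrame) -> None:
        required = {"cell_id", "input", "output", "subtype"} | set(_METRIC_COLUMNS.values())
        missing = required - set(cells.columns)
        if missing:
            raise ConfigurationError(f"cell metrics table missing columns {sorted(missing)}")
        bad_in = set(cells["input"]) - set(INPUT_REGIONS)
        bad_out = set(cells["output"]) - set(OUTPUT_REGIONS)
        bad_sub = set(cells["subtype"]) - set(SUBTYPES)
        if bad_in or bad_out or bad_sub:
            raise LabelingError(
                f"unknown labels: inputs {sorted(bad_in)}, outputs {sorted(bad_out)}, subtypes {sorted(bad_sub)}"
            )
        self.cells = cells.reset_index(drop=True)
        self.summary = self._summarize()

    def _summarize(self) -> pd.DataFrame:
        rows = []
        grouped = self.cells.groupby(["subtype", "input", "output"])
        groups = {key: df for key, df in grouped}
        for metric, col in _METRIC_COLUMNS.items():
            for subtype in SUBTYPES:
                for inp in INPUT_REGIONS:
                    for out in OUTPUT_REGIONS:
                        df = groups.get((subtype, inp, out))
                        if df is None or len(df) == 0:
                            rows.append((metric, subtype, inp, out, np.nan, np.nan, 0))
                            continue
                        vals = df[col].to_numpy(float)
                        n = vals.size
                        mean = float(vals.mean())
                        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
                        rows.append((metric, subtype, inp, out, mean, sem, n))
        return pd.DataFrame(rows, columns=["metric", "subtype", "input", "output", "mean", "sem", "n"])

    def values(self, metric: str, subtype: str, input_region: str, output_region: str) -> np.ndarray:
        """Per-cell values for one matrix entry."""
        col = _METRIC_COLUMNS[metric]
        sel = self.cells[
            (self.cells["subtype"] == subtype)
            & (self.cells["input"] == input_region)
            & (self.cells["output"] == output_region)
        ]
        return sel[col].to_numpy(float)

    def long_values(self, metric: str, subtype: str) -> pd.DataFrame:
        """All per-cell values for one metric/subtype as a long table."""
        col = _METRIC_COLUMNS[metric]
        sel = self.cells[self.cells["subtype"] == subtype]
        out = sel[["cell_id", "input", "output", col]].rename(columns={col: "value"})
        if "auc_0mw" in sel.columns:
            out = out.assign(reference=sel["auc_0mw"].to_numpy(float))
        return out.reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        """Summary in the reference-table schema (directly diffable)."""
        self.summary.to_csv(path, index=False)

    def cells_to_csv(self, path: str | Path) -> None:
        self.cells.to_csv(path, index=False)

    def heatmap(self, metric: str = "auc", subtype: str = "I", ax=None):
        """Mean-strength heatmap (inputs x outputs) for one metric/subtype."""
        import matplotlib.pyplot as plt

        sub = self.summary[(self.summary["metric"] == metric) & (self.summary["subtype"] == subtype)]
        grid = sub.pivot(index="input", columns="output", values="mean")
        grid = grid.reindex(index=list(INPUT_REGIONS), columns=list(OUTPUT_REGIONS))
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        im = ax.imshow(grid.to_numpy(float), aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(OUTPUT_REGIONS)), OUTPUT_REGIONS, rotation=45)
        ax.set_yticks(range(len(INPUT_REGIONS)), INPUT_REGIONS)
        ax.set_xlabel("output region")
        ax.set_ylabel("input region")
        ax.set_title(f"{metric}, type {subtype}")
        ax.figure.colorbar(im, ax=ax)
        return ax


def assemble_matrix(cell_metrics: pd.DataFrame) -> StrengthMatrix:
    """Build the strength matrix from a tidy per-cell metrics table.

    Rows with a ``qc_status`` other than ``pass`` are excluded; entries with
    fewer than two cells report a mean but no SEM and are skipped by the
    inferential stages.
    """
    df = cell_metrics
    if "qc_status" in df.columns:
        df = df[df["qc_status"] == "pass"]
    return StrengthMatrix(df)
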