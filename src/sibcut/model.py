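"""Model/Results facade over the PLS machinery.

:class:`PotencyModel` holds an encoded dataset (or builds one from
records / a DataFrame plus a descriptor table); :meth:`PotencyModel.fit`
returns a :class:`PotencyResults` carrying coefficients, training
diagnostics and prediction methods, with a printable ``summary()``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .bcut import DescriptorTable, natural_descriptor_table
from .encoding import (
    EncodedDataset,
    SiRNARecord,
    encode_dataset,
    encode_sirna,
    tokenize_sequence,
)
from .pls import EvaluationReport, PLSConfig, PLSModel, fit_pls


class PotencyModel:
    """siRNA potency regression on concatenated BCUT descriptors."""

    def __init__(self, data: EncodedDataset, table: DescriptorTable | None = None):
        if data.n_samples < 2:
            raise ValueError("need at least 2 siRNAs to model potency")
        self.data = data
        self.table = table

    @classmethod
    def from_records(
        cls, records: Sequence[SiRNARecord], table: DescriptorTable | None = None
    ) -> "PotencyModel":
        table = table if table is not None else natural_descriptor_table()
        return cls(encode_dataset(records, table), table)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        table: DescriptorTable | None = None,
        *,
        id_col: str = "id",
        sequence_col: str = "sequence",
        potency_col: str = "potency",
    ) -> "PotencyModel":
        records = [
            SiRNARecord(
                str(row[id_col]),
                tokenize_sequence(str(row[sequence_col])),
                float(row[potency_col]),
            )
            for _, row in frame.iterrows()
        ]
        return cls.from_records(records, table)

    @property
    def endog(self) -> np.ndarray:
        return self.data.y

    @property
    def exog(self) -> np.ndarray:
        return self.data.X

    def fit(self, n_components: int | str = "all", scale: bool = True) -> "PotencyResults":
        cfg = PLSConfig(n_components=n_components, scale=scale)
        pls = fit_pls(self.data.X, self.data.y, cfg, column_labels=self.data.columns)
        return PotencyResults(self, pls)


class PotencyResults:
    """Fitted potency model: coefficients, diagnostics, prediction."""

    def __init__(self, model: PotencyModel, pls: PLSModel):
        self.model = model
        self.pls = pls
        self.fittedvalues = pls.predict(model.data.X)
        self.train_report = EvaluationReport.from_predictions(model.data.y, self.fittedvalues)

    @property
    def params(self) -> pd.Series:
        """Regression coefficients in autoscaled descriptor space."""
        return pd.Series(self.pls.coefficients, index=self.pls.column_labels)

    @property
    def n_components_used(self) -> int:
        return self.pls.n_components_used

    def _encode(self, data) -> np.ndarray:
        if isinstance(data, EncodedDataset):
            return data.X
        if isinstance(data, np.ndarray):
            return data
        if isinstance(data, str):
            data = [data]
        table = self.model.table
        if table is None:
            raise ValueError("model was built without a descriptor table; pass a matrix")
        rows = []
        for item in data:
            if isinstance(item, SiRNARecord):
                tokens = item.sequence
            elif isinstance(item, str):
                tokens = tokenize_sequence(item)
            else:
                tokens = tuple(item)
            rows.append(encode_sirna(tokens, table))
        return np.vstack(rows)

    def predict(self, data) -> np.ndarray:
        """Predict potency for a matrix, encoded dataset, or sequences."""
        return self.pls.predict(self._encode(data))

    def evaluate(self, data, y=None) -> EvaluationReport:
        if isinstance(data, EncodedDataset) and y is None:
            y = data.y
        if y is None:
            raise ValueError("actual potencies required for evaluation")
        return EvaluationReport.from_predictions(np.asarray(y, float), self.predict(data))

    def save(self, path) -> None:
        self.pls.to_json(path)

    def summary(self) -> str:
        rep = self.train_report
        lines = [
            "siRNA BCUT potency model (PLS)",
            "=" * 46,
            f"{'No. siRNAs:':<28}{rep.n}",
            f"{'Sequence length:':<28}{self.model.data.sequence_length}",
            f"{'Descriptors:':<28}{self.model.data.X.shape[1]}",
            f"{'Components requested:':<28}{self.pls.config.n_components}",
            f"{'Components used:':<28}{self.n_components_used}",
            f"{'Autoscaled:':<28}{self.pls.config.scale}",
            "-" * 46,
            f"{'Training Pearson r:':<28}{rep.r:.4f}",
            f"{'Training predictive r2:':<28}{rep.r2:.4f}",
            f"{'Training RMSE:':<28}{rep.rmse:.4f}",
            "-" * 46,
            "Largest |coefficient| (autoscaled space):",
        ]
        top = self.params.abs().nlargest(5)
        for label in top.index:
            lines.append(f"  {label:<24}{self.params[label]:+.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PotencyResults n={self.train_report.n} "
            f"components={self.n_components_used} r={self.train_report.r:.3f}>"
        )
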