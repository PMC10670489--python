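"""Blind prediction on unlabeled spectra and model comparison.

Given any trained classifier exposing ``predict``/``confidence``, a blind
(mixture) set is scored at the spectrum level: each spectrum casts a class
vote, rejected spectra (confidence below the optional threshold) are
excluded from the denominator, and the tumor percentage over the
non-rejected votes estimates the tumor fraction of the cell mixture.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .spectra import TUMOR, SpectrumSet

__all__ = ["MixtureReport", "blind_predict", "compare_models",
           "expected_mixture_estimate"]


@dataclasses.dataclass
class MixtureReport:
    model_name: str
    n_spectra: int
    n_predicted_tumor: int
    n_predicted_nontumor: int
    n_rejected: int
    percent_tumor: float | None     # None when every spectrum was rejected
    nominal_percent: float | None
    per_spectrum_votes: list[str]

    def __post_init__(self) -> None:
        assert (self.n_predicted_tumor + self.n_predicted_nontumor
                + self.n_rejected) == self.n_spectra, "votes not conserved"


def blind_predict(
    model,
    spectrum_set: SpectrumSet,
    reject_threshold: float | None = None,
) -> MixtureReport:
    """Spectrum-level class votes and estimated tumor percentage.

    If both the model and the set carry a preprocessing-configuration
    hash, they must match ("same instrument setup, procedures and
    parameters"); a mismatch raises.
    """
    model_hash = getattr(model, "preprocess_hash", None)
    set_hash = spectrum_set.meta.get("preprocess_hash")
    if model_hash is not None and set_hash is not None and model_hash != set_hash:
        raise ValueError(
            "blind set was preprocessed with a different configuration "
            "than the training data"
        )
    X = spectrum_set.to_matrix()
    labels = np.asarray(model.predict(X))
    if reject_threshold is not None:
        conf = np.asarray(model.confidence(X))
        accept = conf >= reject_threshold
    else:
        accept = np.ones(len(labels), dtype=bool)
    votes = [l if a else "REJECT" for l, a in zip(labels, accept)]
    n_tum = int(np.sum(labels[accept] == TUMOR))
    n_non = int(accept.sum()) - n_tum
    n_rej = int((~accept).sum())
    percent = 100.0 * n_tum / (n_tum + n_non) if (n_tum + n_non) else None
    return MixtureReport(
        model_name=getattr(model, "name", type(model).__name__),
        n_spectra=len(labels),
        n_predicted_tumor=n_tum,
        n_predicted_nontumor=n_non,
        n_rejected=n_rej,
        percent_tumor=percent,
        nominal_percent=spectrum_set.meta.get("nominal_tumor_pct"),
        per_spectrum_votes=votes,
    )


def expected_mixture_estimate(p: float, sensitivity: float,
                              specificity: float) -> float:
    """Large-sample limit of the vote-counting estimate: a fraction ``p``
    of true tumor spectra classified with the given per-class accuracies
    yields an expected tumor-vote fraction p*sens + (1-p)*(1-spec)."""
    return p * sensitivity + (1.0 - p) * (1.0 - specificity)


def compare_models(
    reports: dict[str, list[MixtureReport]],
    set_names: list[str] | None = None,
) -> tuple[pd.DataFrame, str]:
    """Tabular comparison (rows = models, columns = blind sets).

    ``reports`` maps model name -> list of reports, one per blind set in
    declared order.  Returns the table and a deterministic plain-text
    rendering.
    """
    if not reports:
        raise ValueError("at least one model report is required")
    n_sets = len(next(iter(reports.values())))
    if set_names is None:
        set_names = [f"set{i+1}" for i in range(n_sets)]
    rows = {}
    nominal_row = None
    for model_name, model_reports in reports.items():
        if len(model_reports) != n_sets:
            raise ValueError("every model needs one report per blind set")
        rows[model_name] = [
            (np.nan if r.percent_tumor is None else round(r.percent_tumor, 2))
            for r in model_reports
        ]
        if nominal_row is None and all(
            r.nominal_percent is not None for r in model_reports
        ):
            nominal_row = [round(r.nominal_percent, 2) for r in model_reports]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=set_names)
    if nominal_row is not None:
        table = pd.concat(
            [pd.DataFrame([nominal_row], index=["Nominal"], columns=set_names),
             table]
        )
    lines = ["Blind mixture comparison (% spectra voted Tumor)", ""]
    header = "model".ljust(28) + "".join(n.rjust(12) for n in set_names)
    lines.append(header)
    for name, vals in table.iterrows():
        lines.append(
            name.ljust(28)
            + "".join(
                (f"{v:.2f}" if np.isfinite(v) else "n/a").rjust(12) for v in vals
            )
        )
    return table, "\n".join(lines) + "\n"
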