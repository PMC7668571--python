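"""Bench-validation harness: dual test-lung experiments vs model predictions.

Five dual-lung validation runs were performed on a clinical ventilator in
pressure-control mode (PEEP 5 cmH2O, RR 15/min, I:E 1:2), varying the
inspiratory pressure and the restrictor placed in Lung 1's inspiratory limb:

====  ======  =========================================
test  Pinsp   Lung 1 inspiratory restrictor
====  ======  =========================================
1     25      none
2     25      non-return valve, 12 cmH2O/(L/s)
3     25      small orifice restrictor, 33 cmH2O/(L/s)
4     15      none
5     15      non-return valve, 12 cmH2O/(L/s)
====  ======  =========================================

Lung 2's branch is never restricted, so its prediction is constant across
tests 1-3 and across tests 4-5.  Component parameters came from bench
characterisation: tubing Rv = 22 cmH2O/(L/s), Cv = 0.004 L/cmH2O; Lung 1
R = 12, C = 0.040; Lung 2 R = 10, C = 0.030.

:func:`run_validation` recomputes every prediction with the cyclic
steady-state solver and compares against the measured tidal volumes
(bench values, mean over 15 cycles), reporting per-case percentage
deviations 100 (measured - predicted) / predicted and their summary
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rc_core import CircuitParams, LungParams, VentSettings, cyclic_steady_state

__all__ = [
    "LUNG_1",
    "LUNG_2",
    "TUBING",
    "VALIDATION_TESTS",
    "MEASURED_VT",
    "ValidationReport",
    "run_validation",
    "measured_reduction_pct",
]

#: Bench-characterised component parameters.
LUNG_1 = LungParams(r=12.0, c=0.040)
LUNG_2 = LungParams(r=10.0, c=0.030)
TUBING = dict(r_v=22.0, c_v=0.004)

#: (test number, Pinsp cmH2O, Lung-1 inspiratory restrictor cmH2O/(L/s)).
VALIDATION_TESTS = (
    (1, 25.0, 0.0),
    (2, 25.0, 12.0),
    (3, 25.0, 33.0),
    (4, 15.0, 0.0),
    (5, 15.0, 12.0),
)

#: Measured tidal volumes (L), mean over 15 cycles, per (test, lung).
MEASURED_VT = {
    ("Lung 1", 1): 0.554,
    ("Lung 1", 2): 0.433,
    ("Lung 1", 3): 0.357,
    ("Lung 1", 4): 0.306,
    ("Lung 1", 5): 0.245,
    ("Lung 2", 1): 0.498,
    ("Lung 2", 2): 0.515,
    ("Lung 2", 3): 0.522,
    ("Lung 2", 4): 0.282,
    ("Lung 2", 5): 0.299,
}

PEEP = 5.0
RR = 15.0
IE_E = 2.0


@dataclass(frozen=True)
class ValidationReport:
    """Predicted-vs-measured comparison over all ten lung/test cases."""

    frame: pd.DataFrame
    mean_abs_deviation_pct: float
    min_abs_deviation_pct: float
    max_abs_deviation_pct: float

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __str__(self) -> str:
        lines = [
            self.frame.to_string(
                index=False,
                formatters={
                    "predicted_vt": "{:.3f}".format,
                    "measured_vt": "{:.3f}".format,
                    "deviation_pct": "{:+.1f}".format,
                },
            ),
            "",
            (
                f"absolute deviation: mean {self.mean_abs_deviation_pct:.1f}%  "
                f"min {self.min_abs_deviation_pct:.1f}%  "
                f"max {self.max_abs_deviation_pct:.1f}%"
            ),
        ]
        return "\n".join(lines)


def predict_case(pinsp: float, lung: LungParams, r_restrictor: float) -> float:
    """Model-predicted tidal volume for one validation configuration."""
    settings = VentSettings(pinsp=pinsp, peep=PEEP, rr=RR, ie_e=IE_E)
    circuit = CircuitParams(r_restrictor_insp=r_restrictor, **TUBING)
    return cyclic_steady_state(lung, circuit, settings).vt


def run_validation() -> ValidationReport:
    """Recompute all ten predictions and compare with the measured volumes.

    Deviation is 100 (measured - predicted) / predicted; the summary reports
    the mean, min and max of the absolute deviations over the ten cases.
    """
    rows = []
    for lung_label, lung in (("Lung 1", LUNG_1), ("Lung 2", LUNG_2)):
        for test, pinsp, restrictor in VALIDATION_TESTS:
            r_r = restrictor if lung_label == "Lung 1" else 0.0
            predicted = predict_case(pinsp, lung, r_r)
            measured = MEASURED_VT[(lung_label, test)]
            rows.append(
                {
                    "test": test,
                    "lung": lung_label,
                    "pinsp": pinsp,
                    "r_restrictor": r_r,
                    "predicted_vt": predicted,
                    "measured_vt": measured,
                    "deviation_pct": 100.0 * (measured - predicted) / predicted,
                }
            )
    frame = pd.DataFrame(rows)
    abs_dev = frame["deviation_pct"].abs()
    return ValidationReport(
        frame=frame,
        mean_abs_deviation_pct=float(abs_dev.mean()),
        min_abs_deviation_pct=float(abs_dev.min()),
        max_abs_deviation_pct=float(abs_dev.max()),
    )


def measured_reduction_pct(test_from: int, test_to: int, lung: str = "Lung 1") -> int:
    """Measured tidal-volume reduction between two tests, rounded percent.

    E.g. the non-return valve (test 2 vs 1) and the small orifice restrictor
    (test 3 vs 1) reduce Lung 1's measured volume by 22% and 36%.
    """
    v0 = MEASURED_VT[(lung, test_from)]
    v1 = MEASURED_VT[(lung, test_to)]
    return int(round(100.0 * (v0 - v1) / v0))
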