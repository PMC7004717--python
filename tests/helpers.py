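"""Shared test utilities: synthetic regression tables with known truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

# data-generating coefficients for the recovery studies
TRUE_BETAS = {
    "method[T.CAI]": -0.05,
    "method[T.SpEn]": 0.05,
    "sex[T.M]": -0.1,
    "age": -0.004,
    "bmi": -0.5,
    "time": -1e-4,
}
TRUE_INTERCEPT = 12.0
NOISE_SD = 0.3


def make_long_table(
    rng: np.random.Generator,
    n_subjects: int = 25,
    n_times: int = 67,
    t_max: float = 5000.0,
    smooth_amp: float = 0.3,
    smooth_cycles: int = 3,
) -> pd.DataFrame:
    """Long-format table from known coefficients plus a sinusoidal smooth.

    Rows: subjects x methods (BIS/CAI/SpEn) x a shared regular time grid
    (~n_subjects*3*n_times rows).  The smooth is a whole number of
    cosine cycles over [0, t_max], so it is orthogonal to the intercept
    and the linear time term and the parametric truth is identifiable.
    Noise is iid Gaussian with sd ``NOISE_SD``.
    """
    t = np.linspace(0.0, t_max, n_times)
    smooth = smooth_amp * np.cos(2 * np.pi * smooth_cycles * t / t_max)
    rows = []
    for i in range(n_subjects):
        sex = "M" if rng.random() < 0.5 else "F"
        age = float(rng.uniform(20, 75))
        bmi = float(rng.uniform(18, 32))
        for method in ("BIS", "CAI", "SpEn"):
            z = (
                TRUE_INTERCEPT
                + TRUE_BETAS["method[T.CAI]"] * (method == "CAI")
                + TRUE_BETAS["method[T.SpEn]"] * (method == "SpEn")
                + TRUE_BETAS["sex[T.M]"] * (sex == "M")
                + TRUE_BETAS["age"] * age
                + TRUE_BETAS["bmi"] * bmi
                + TRUE_BETAS["time"] * t
                + smooth
                + rng.normal(0.0, NOISE_SD, t.size)
            )
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": f"s{i:02d}",
                        "method": method,
                        "time": t,
                        "z": z,
                        "sex": sex,
                        "age": age,
                        "bmi": bmi,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def seed_from(*parts: int) -> int:
    """Deterministic sub-seed below 2**31 derived from integer parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)
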