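"""Mixed-type clinical table tied to a latent severity."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig

#: cycle of roles for generated continuous variables
_CONT_ROLES = ("neuropsych", "imaging")

DIAGNOSIS_LEVELS = ("CN", "EMCI", "LMCI")


def simulate_clinical(
    config: SimulationConfig,
    latent_severity: np.ndarray,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulate ``n_clinical`` baseline variables correlated with severity.

    Continuous scores are affine transforms of the latent severity plus
    Gaussian noise, tagged alternately as neuro-psychological and imaging
    variables. Age is drawn independently of severity (demographic); education
    is an independent ordinal (demographic); the baseline diagnosis
    (CN / EMCI / LMCI) is assigned by severity tertile thresholds.

    Returns the table and a column -> role mapping with roles drawn from
    {demographic, age, education, diagnosis, neuropsych, imaging}.
    """
    severity = np.asarray(latent_severity, dtype=float)
    if severity.shape[0] != config.n_patients:
        raise ValueError("latent severity length must equal n_patients")
    rng = config.rng("clinical")
    idx = [f"P{i:04d}" for i in range(config.n_patients)]
    cols: dict[str, np.ndarray | pd.Categorical] = {}
    roles: dict[str, str] = {}
    if config.n_clinical == 0:
        return pd.DataFrame(index=idx), roles

    n_fixed = 3  # age, education, diagnosis
    n_cont = max(config.n_clinical - n_fixed, 0)
    for j in range(n_cont):
        role = _CONT_ROLES[j % len(_CONT_ROLES)]
        a = rng.uniform(-2, 2)
        b = rng.uniform(0.5, 2.0) * (1 if rng.random() < 0.5 else -1)
        name = f"{'NP' if role == 'neuropsych' else 'IMG'}{j:03d}"
        cols[name] = a + b * severity + noise_sd * rng.standard_normal(len(severity))
        roles[name] = role

    cols["AGE"] = rng.normal(73.0, 6.0, size=len(severity))
    roles["AGE"] = "age"
    cols["EDUCATION"] = rng.integers(8, 21, size=len(severity)).astype(float)
    roles["EDUCATION"] = "education"
    t1, t2 = np.quantile(severity, [1 / 3, 2 / 3])
    diag = np.where(severity <= t1, "CN", np.where(severity <= t2, "EMCI", "LMCI"))
    cols["DX"] = pd.Categorical(diag, categories=list(DIAGNOSIS_LEVELS), ordered=True)
    roles["DX"] = "diagnosis"

    table = pd.DataFrame(cols, index=idx)
    return table, roles
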