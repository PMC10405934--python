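"""Two-way deterministic sensitivity analysis: the CE-CT breaking point.

Maps the cost-effective strategy (max net monetary benefit at $100,000/QALY)
over a grid of CE-CT sensitivity (y) against MRI sensitivity (x).  MRI wins
nearly everywhere; a CE-CT region appears only where CE-CT sensitivity is
pushed far above its observed value while MRI sensitivity falls well below
its own — the hypothetical "breaking point".
"""

from pathlib import Path

import numpy as np

from crlm_cea.sensitivity import two_way

import importlib.util

spec = importlib.util.spec_from_file_location(
    "basecase", Path(__file__).with_name("01_basecase.py")
)
basecase = importlib.util.module_from_spec(spec)
spec.loader.exec_module(basecase)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table, lifetable = basecase.calibrated_inputs()
    grid_mri = np.round(np.linspace(0.40, 1.00, 13), 3)
    grid_cect = np.round(np.linspace(0.40, 1.00, 13), 3)
    df = two_way("sens_mri", "sens_cect", grid_mri, grid_cect, table, lifetable)
    df.index.name = "sens_cect"
    df.to_csv(RESULTS / "twoway_sensitivity.csv")
    counts = df.stack().value_counts()
    print(df.to_string())
    print("\ncells won:", counts.to_dict())


if __name__ == "__main__":
    main()
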