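"""Emergence timing and synchronization: activity-weighted median day of
year, quartiles and IQR per species, plus the cross-species regressions
(timing ~ residual activity, synchronization ~ timing).

Reads results/fits/ and results/model_frame.csv, writes results/emergence/.
"""

from pathlib import Path

import pandas as pd

from batemerge import io as bio
from batemerge.emergence import (
    cross_species_regression,
    daily_predicted_activity,
    emergence_summary,
)
from batemerge.residuals import residual_activity

FITS = Path("results/fits")
OUT = Path("results/emergence")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    frame = bio.read_model_frame("results/model_frame.csv")
    summaries = []
    for bundle in sorted(FITS.glob("model_*.json")):
        fit = bio.load_model(bundle)
        sub = frame[frame.species == fit.species].reset_index(drop=True)
        daily = daily_predicted_activity(fit, sub)
        summaries.append(emergence_summary(daily, residual_activity(fit)))
    tab = pd.DataFrame([s.__dict__ for s in summaries]).sort_values("median_doy")
    tab.to_csv(OUT / "emergence_summary.csv", index=False,
               float_format="%.6f")
    print(tab[["species", "median_doy", "q1", "q3", "iqr"]]
          .to_string(index=False))
    reg = cross_species_regression(summaries)
    reg.reset_index().to_csv(OUT / "cross_species_regressions.csv",
                             index=False, float_format="%.6f")
    print()
    print(reg.to_string())
    print(f"\nsummaries and regressions -> {OUT}/")


if __name__ == "__main__":
    main()
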