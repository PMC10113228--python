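"""Residual (weather-independent) activity per species and functional
groups: ranking by median absolute residual activity, pairwise rank tests
with Bonferroni correction, compact letter display, HRA/MRA/LRA labels.

Reads results/fits/, writes results/residuals/.
"""

from pathlib import Path

import pandas as pd

from batemerge import io as bio
from batemerge.residuals import classify_groups, median_abs_residual, residual_activity

FITS = Path("results/fits")
OUT = Path("results/residuals")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    curves = []
    for bundle in sorted(FITS.glob("model_*.json")):
        fit = bio.load_model(bundle)
        curve = residual_activity(fit)
        curves.append(curve)
        curve.to_frame().to_csv(OUT / f"curve_{curve.species}.csv",
                                index=False, float_format="%.6f")
    groups = classify_groups(curves)
    report = pd.DataFrame({
        "species": groups.ranking,
        "median_abs_residual": [groups.medians[s] for s in groups.ranking],
        "letters": [groups.letters[s] for s in groups.ranking],
        "label": [groups.labels[s] for s in groups.ranking],
    })
    report.to_csv(OUT / "group_report.csv", index=False, float_format="%.6f")
    groups.p_matrix.to_csv(OUT / "p_matrix.csv", float_format="%.6f")
    print(report.to_string(index=False))
    print(f"\nomnibus Kruskal-Wallis p = {groups.omnibus_p:.2e}")
    print(f"curves, report, p-matrix -> {OUT}/")


if __name__ == "__main__":
    main()
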