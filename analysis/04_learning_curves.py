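"""Learning curves: cross-validated R2 as training size grows, summarised by
least-squares fits of six nonlinear trend models compared with AIC.  The
reciprocal model y = a + b/x captures the plateau typical of these curves."""

import sys
from pathlib import Path

import pandas as pd

from opsinpred.experiments import fit_curves, learning_curve
from opsinpred.seqdata import load_dataset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = load_dataset(ROOT / "study" / "sequences.fasta", ROOT / "study" / "metadata.tsv")
    pts = learning_curve(ds, step=30, reps=3, estimator="gbr", seed=SEED, k=5)
    pts.round(4).to_csv(ROOT / "learning_curve.tsv", sep="\t", index=False)
    mean_curve = pts.groupby("n_train")["r2"].mean().reset_index()
    fits = fit_curves(mean_curve)
    rows = [
        {"model": f.name, "aic": f.aic, "rss": f.rss, "ok": f.ok, **f.params}
        for f in fits
    ]
    pd.DataFrame(rows).round(4).to_csv(ROOT / "curve_fits.tsv", sep="\t", index=False)
    print("mean CV R2 by training size:")
    print(mean_curve.round(3).to_string(index=False))
    best = fits[0]
    print(f"\nbest trend model by AIC: {best.name} {best.params}")
    print(f"wrote {ROOT / 'learning_curve.tsv'} and {ROOT / 'curve_fits.tsv'}")


if __name__ == "__main__":
    main()
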