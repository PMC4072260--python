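#!/usr/bin/env python
"""Calibration experiments behind the pipeline's guarantees.

Three desk-scale experiments: (1) the color-deconvolution round trip, showing
unmixing is exact up to 8-bit quantization; (2) the stereology grid over 1000
random offsets, showing the estimator is unbiased and its spread matches the
Weibel (binomial) prediction; (3) classifier recovery across a noisy test
cohort.  Writes results/calibration.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
from scipy import stats

import fibroquant as fq
from fibroquant.pattern_classifier import (
    classify_tile,
    regions_from_phantom,
    tissue_fibrosis_pct,
    train_classifier,
)
from fibroquant.stain_deconvolution import StainMatrix, deconvolve, rgb_to_od
from fibroquant.stereology import point_count_on_phantom


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=2024)
    ap.add_argument("--out", type=Path, default=Path("results/calibration.json"))
    args = ap.parse_args()
    seed = args.seed
    sm = fq.default_stain_model()
    matrix = StainMatrix(sm.od_vectors)
    out = {}

    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(50):
        ph = fq.generate_phantom(64, 64, float(rng.uniform(0, 1)), seed=int(rng.integers(2**31)))
        tile = fq.render_trichrome(ph, sm, noise_sd=0.0, seed=i)
        conc = deconvolve(rgb_to_od(tile, sm.background_intensity), matrix)
        for c, a in sm.mean_od_per_class.items():
            mask = ph.label_map == c
            if mask.any():
                worst = max(worst, float(np.abs(conc[mask] - a).max()))
    out["deconv_max_od_error_after_quantization"] = worst
    print(f"deconvolution round trip: max stain-amount error {worst:.4f} OD (8-bit limited)")

    ph = fq.generate_phantom(2000, 2000, 0.15, seed=seed + 1)
    truth = ph.fibrosis_fraction_of_tissue
    ests, n_eff = [], []
    for i in range(1000):
        r = point_count_on_phantom(ph, 200, 20, "random", seed=seed + 10 + i)
        ests.append(r.fraction)
        n_eff.append(r.n_effective)
    ests = np.asarray(ests)
    pred = float(np.sqrt(truth * (1 - truth) / np.mean(n_eff)))
    out["stereology_bias_pct"] = 100.0 * (float(ests.mean()) - truth)
    out["stereology_sd_ratio_vs_weibel"] = float(ests.std(ddof=1)) / pred
    print(
        f"stereology (interval 200, {len(ests)} random offsets, ~{np.mean(n_eff):.0f} "
        f"effective points): bias {out['stereology_bias_pct']:+.3f} pp, "
        f"SD/Weibel {out['stereology_sd_ratio_vs_weibel']:.3f}"
    )

    regions = []
    for j, f in enumerate((0.1, 0.4, 0.7)):
        phj = fq.generate_phantom(192, 192, f, seed=seed + 900 + j)
        tilej = fq.render_trichrome(phj, sm, noise_sd=0.02, seed=seed + 910 + j)
        regions.extend(regions_from_phantom(phj, tilej, max_pixels_per_class=3000, seed=seed + 920 + j))
    model, report = train_classifier(regions, seed=seed)
    truths, ests = [], []
    for i in range(20):
        phi = fq.generate_phantom(192, 192, 0.9 * i / 19, seed=seed + 1000 + i)
        tilei = fq.render_trichrome(phi, sm, noise_sd=0.02, seed=seed + 1100 + i)
        truths.append(100.0 * phi.fibrosis_fraction_of_tissue)
        ests.append(tissue_fibrosis_pct(classify_tile(tilei, model)))
    r = float(stats.pearsonr(np.asarray(ests), np.asarray(truths)).statistic)
    out["classifier_training_accuracy"] = report.training_accuracy
    out["classifier_r_vs_truth"] = r
    print(
        f"classifier: training accuracy {100 * report.training_accuracy:.2f}%, "
        f"r vs truth {r:.4f} over 20 noisy tiles"
    )

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2))
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
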