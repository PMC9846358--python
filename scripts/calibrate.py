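"""Freeze the architecture constants against the published accounting.

The stage repeat counts (n2, n3, n4) and the inverted-bottleneck ratio t are
figure-only information and cannot be read from the text; the published
multiply-add count (10.1 GFLOPs), weight-file size (8.3 MB) and volume
reduction versus the baseline (39.4%) are the hard constraints.  This script
enumerates candidate configurations, scores each by its worst relative error
over those three quantities, and prints the ranking.  The winning values are
frozen in ``yolop.assembly`` (DEFAULT_STAGE_REPEATS, DEFAULT_EXPANSION) and
never changed afterwards.

Run from the repository root:  python scripts/calibrate.py
"""

import itertools

from yolop.assembly import (ArchSpec, build_variant, build_yolop, count_flops,
                            serialized_volume)

TARGET_FLOPS_G = 10.1
TARGET_VOL_MB = 8.3
TARGET_REDUCTION = 0.394


def score(n2, n3, n4, t, baseline_vol):
    spec = ArchSpec(stage_repeats=(n2, n3, n4), expansion=t)
    model = build_yolop(spec=spec)
    fl = count_flops(model) / 1e9
    vol = serialized_volume(model)
    red = 1.0 - vol / baseline_vol
    errs = (abs(fl - TARGET_FLOPS_G) / TARGET_FLOPS_G,
            abs(vol - TARGET_VOL_MB) / TARGET_VOL_MB,
            abs(red - TARGET_REDUCTION) / TARGET_REDUCTION)
    return max(errs), fl, vol, red


def main():
    baseline = build_variant("yolov5s")
    bvol = serialized_volume(baseline)
    bfl = count_flops(baseline) / 1e9
    print(f"baseline yolov5s: {bfl:.2f} GFLOPs, {bvol:.2f} MB")
    results = []
    # plausible design range: shallow stages carry most repeats (the stated
    # motive is cheap high-resolution capacity), deep stage stays short
    for n2, n3, n4 in itertools.product(range(8, 14), range(5, 12), range(1, 5)):
        for t in (1 / 3, 0.5, 2 / 3):
            results.append(((n2, n3, n4), t, *score(n2, n3, n4, t, bvol)))
    results.sort(key=lambda r: r[2])
    print("top candidates (worst-case relative error):")
    for (reps, t, err, fl, vol, red) in results[:10]:
        print(f"  repeats={reps} t={t:.3f}: err={err:.3%} "
              f"flops={fl:.2f}G vol={vol:.2f}MB reduction={red:.1%}")


if __name__ == "__main__":
    main()
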