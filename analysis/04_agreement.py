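"""Cross-software robustness of the 16 radiomic metrics.

Reads features.csv; computes pairwise Pearson r and Bland-Altman summaries
per site, the average r and its CV per metric, and the three-rater
ICC(2,1) per site; prints the agreement ranking.
"""
import pandas as pd

from common import outdir, study_args
from ivimrad.agreement import agreement_study, pairs_frame, summaries_frame
from ivimrad.pipeline import _FLOAT_FMT


def main() -> None:
    args = study_args(__doc__)
    out = outdir(args)
    features = pd.read_csv(out / "features.csv")
    summaries, records = agreement_study(features)
    summaries_frame(summaries).to_csv(out / "agreement_summary.csv",
                                      index=False, float_format=_FLOAT_FMT)
    pairs_frame(records).to_csv(out / "agreement_pairs.csv", index=False,
                                float_format=_FLOAT_FMT)
    print("metric ranking by mean inter-software Pearson r "
          "(over 3 pairs x 3 sites):")
    for s in summaries:
        print(f"  {s.rank:2d}. {s.metric_name:14s} mean r = {s.mean_r:.3f}  "
              f"CV = {s.cv_r_pct:.1f}%")
    dt_mean = next(s for s in summaries if s.metric_name == "D_t_mean")
    dp_mean = next(s for s in summaries if s.metric_name == "D_p_mean")
    print(f"\nD_t_mean (r={dt_mean.mean_r:.3f}) vs D_p_mean "
          f"(r={dp_mean.mean_r:.3f}): tissue-diffusivity radiomics travel "
          "across fitting algorithms far better than pseudo-diffusion ones.")


if __name__ == "__main__":
    main()
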