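"""Shared bits for the numbered analysis drivers."""
import argparse
from pathlib import Path

from ivimrad import StudyConfig


def study_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--out", default="results/study", help="study directory")
    ap.add_argument("--seed", type=int, default=1, help="master seed")
    ap.add_argument("--config", default=None,
                    help="JSON/YAML study config (default: study defaults)")
    ap.add_argument("--tiny", action="store_true",
                    help="2 benign + 2 malignant per site, for a quick pass")
    return ap.parse_args()


def load_config(args) -> StudyConfig:
    if args.config:
        cfg = StudyConfig.from_file(args.config)
        if cfg.seed != args.seed:
            cfg = StudyConfig.from_dict({**cfg.to_dict(), "seed": args.seed})
        return cfg
    d = {"seed": args.seed}
    if args.tiny:
        d["cohort"] = {"site_counts": {s: (2, 2) for s in "ABC"}}
    return StudyConfig.from_dict(d)


def outdir(args) -> Path:
    p = Path(args.out)
    p.mkdir(parents=True, exist_ok=True)
    return p
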