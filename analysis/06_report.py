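"""Assemble the human-readable study report (report.md).

Requires the tables written by the earlier stages in the study directory.
"""
import json

from common import load_config, outdir, study_args
from ivimrad.pipeline import StudyConfig, StudyReport, render_report


def main() -> None:
    args = study_args(__doc__)
    out = outdir(args)
    cfg = StudyConfig.from_file(out / "config.json") if (out / "config.json").exists() \
        else load_config(args)
    manifest = {k: f"{k}.csv" for k in
                ("features", "utilization", "agreement_summary", "auc_summary")}
    report = StudyReport(out, manifest, cfg)
    text = render_report(report)
    (out / "report.md").write_text(text)
    (out / "manifest.json").write_text(
        json.dumps({**manifest, "report": "report.md"}, indent=2) + "\n")
    print(f"wrote {out}/report.md ({len(text.splitlines())} lines)")


if __name__ == "__main__":
    main()
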