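"""Inter-reader ICC per metric on the simulated primary cohort and the
ICC >= 0.80 reliability gate."""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

from mbdwi.models import METRICS                      # noqa: E402
from mbdwi.reliability import filter_by_icc, icc_table  # noqa: E402

SEED = 11


def main() -> None:
    pairs_path = ROOT / "results" / "cohorts" / "primary_reader_pairs.csv"
    if pairs_path.exists():
        pairs = pd.read_csv(pairs_path)
    else:
        from mbdwi.synthetic import generate_study
        pairs = generate_study(seed=SEED)["primary"].reader_pairs
    icc = icc_table(pairs[pairs.metric.isin(METRICS)])
    icc.to_csv(OUT / "icc_table.csv", index=False)
    retained = filter_by_icc(icc, 0.80, metrics=list(METRICS))
    print(icc.sort_values("icc").to_string(index=False))
    print(f"retained {len(retained)}/18 metrics at ICC >= 0.80")


if __name__ == "__main__":
    main()
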