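"""User identification: from "which code is familiar?" to "who is watching?".

Restricts every session to its familiar-code epochs, profiles a multi-class
density model over the users' identities and estimates PI(U; O) with
cross-validation (reduction refitted inside each fold).  Writes
results/identification.csv.
"""

from pathlib import Path

import pandas as pd

import erpleak as el
from cohort import build_cohort

ROOT = Path(__file__).resolve().parents[1]


def main():
    (ROOT / "results").mkdir(exist_ok=True)
    cohort = build_cohort()
    sessions = [s for _, s in cohort]

    res = el.identify_user(sessions, cv_k=10, seed=0)
    rows = [{"user": u, "partial_pi": round(v, 4)}
            for u, v in res.partial_pi.items()]
    rows.append({"user": "overall", "partial_pi": round(res.overall_pi, 4)})
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "identification.csv", index=False)

    print(df.to_string(index=False))
    print(f"\nPI(U;O) = {res.overall_pi:.3f} of H[U] = {res.h_prior:.3f} bits "
          f"[{res.ci_low:.3f}, {res.ci_high:.3f}] — the familiar-code epochs "
          "identify the user far better than they reveal the code itself: the "
          "privacy leak exceeds the security leak.")
    print("\nConfusion (true user x predicted):")
    print(res.confusion.to_string())


if __name__ == "__main__":
    main()
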