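"""Longitudinal mixed-model inference.

Per metabolite: concentration ~ region * day with random intercepts for
animal and animal x region; per volume outcome: volume ~ day with an animal
random intercept.  Writes the full contrast table and prints the headline
comparisons (lesional regions vs contralesional, day-14 recovery).
"""

import pandas as pd
from study_config import STUDY

from perispect.pipeline import stage_model

if __name__ == "__main__":
    qc = stage_model(STUDY)
    bad = [k for k, v in qc.items() if k.endswith("converged") and not v]
    if bad:
        print("warning: non-converged fits:", ", ".join(bad))
    tab = pd.read_csv(f"{STUDY.out_dir}/tables/contrasts.csv")
    show = tab[tab.response.isin(["NAA", "Cr", "edema_ml", "hematoma_ml"])]
    pd.set_option("display.width", 120)
    print(show[["response", "contrast", "estimate", "se", "p", "significant"]]
          .round(4).to_string(index=False))
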