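"""Summary figures and the run manifest.

Produces trajectory plots of NAA/Cr/Cho by region and of edema/hematoma
volumes by day (with SEM error bars), and a manifest recording the seed,
config hash, package versions and per-stage QC so the run is reproducible.
"""

import json

import pandas as pd
from study_config import STUDY

from perispect.pipeline import stage_report

if __name__ == "__main__":
    qc = stage_report(STUDY, {})
    print("figures: figures/metabolites_by_day.png, figures/volumes_by_day.png")
    print("manifest:", qc["manifest"])

    # headline narrative: does the recovered cohort show the expected pattern?
    tab = pd.read_csv(f"{STUDY.out_dir}/tables/contrasts.csv")
    naa = tab[tab.response == "NAA"].set_index("contrast")
    phe = naa.loc["PHE day 14 vs day 1"]
    atne = naa.loc["ATNE day 14 vs day 1"]
    print(f"\nNAA PHE day-14 recovery: {phe.estimate:+.2f} mM "
          f"(p = {phe.p:.2g}) -> {'significant' if phe.significant else 'ns'}")
    print(f"NAA ATNE day-14 change:  {atne.estimate:+.2f} mM "
          f"(p = {atne.p:.2g}) -> {'significant' if atne.significant else 'ns'}")
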