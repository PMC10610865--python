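"""Published Hill-curve parameter triples for mambalgin-2 pharmacology.

These are the reported dose-response parameters (IC50 in nM, Bottom as a
fraction of the control current, Hill slope magnitude) for mambalgin-2 and
its 'head' mutants acting on acid-sensing channels expressed in Xenopus
oocytes.  They serve as generative inputs for synthetic curves and as the
reference points of round-trip recovery checks.

Slope signs: a decreasing inhibition curve can be parameterized with
either sign of nH; magnitudes are stored (see `asictox.doseresponse`).
"""

from .doseresponse import HillParams

#: Mambalgin-2 (wild type) at the heterotrimeric alpha-ENaC/ASIC1a/gamma-ENaC
#: channel carrying point mutations in the gamma-ENaC complementary subunit.
GAMMA_ENAC_MUTANT_CHANNELS = {
    "WT": HillParams(ic50_nm=130.0, bottom=0.07, nh=1.6),
    "F89A": HillParams(ic50_nm=150.0, bottom=0.14, nh=2.5),
    "R90A": HillParams(ic50_nm=250.0, bottom=0.18, nh=1.8),
    "K91A": HillParams(ic50_nm=190.0, bottom=0.26, nh=2.1),
}

#: Mambalgin-2 'head' mutants at the wild-type heterotrimeric channel.
TOXIN_MUTANTS_HETEROTRIMER = {
    "WT": HillParams(ic50_nm=130.0, bottom=0.07, nh=1.6),
    "H13A": HillParams(ic50_nm=350.0, bottom=0.07, nh=1.4),
    "R14A": HillParams(ic50_nm=200.0, bottom=0.10, nh=2.2),
    "D15A": HillParams(ic50_nm=230.0, bottom=0.09, nh=2.0),
    "R14A/D15A": HillParams(ic50_nm=220.0, bottom=0.03, nh=1.2),
}

#: Mambalgin-2 'head' mutants at the homotrimeric ASIC1a channel.
TOXIN_MUTANTS_HOMOTRIMER = {
    "WT": HillParams(ic50_nm=310.0, bottom=0.39, nh=2.9),
    "H13A": HillParams(ic50_nm=510.0, bottom=0.28, nh=1.5),
    "R14A": HillParams(ic50_nm=250.0, bottom=0.44, nh=1.7),
    "D15A": HillParams(ic50_nm=300.0, bottom=0.42, nh=1.0),
    "R14A/D15A": HillParams(ic50_nm=470.0, bottom=0.13, nh=1.9),
}

ALL_PARAMETER_SETS = {
    "gamma_enac_mutant_channels": GAMMA_ENAC_MUTANT_CHANNELS,
    "toxin_mutants_heterotrimer": TOXIN_MUTANTS_HETEROTRIMER,
    "toxin_mutants_homotrimer": TOXIN_MUTANTS_HOMOTRIMER,
}
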