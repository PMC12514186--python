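"""Default calibration constants for the synthetic study conditions.

Two constants are calibrated to the measured biology this package targets:
the TV6-vs-TV1 interspecies log2FC slope (0.883) and the replicate count
(4 per species × vertebra). Everything else is a declared synthetic choice
(see docs/methods.md) and is not fitted to any dataset.
"""

# --- paired-lfc fixture / regression calibration -------------------------
SLOPE = 0.883           # TV6-vs-TV1 interspecies log2FC slope
INTERCEPT = 0.0
RESID_SD = 0.25         # log2 scatter of equivalently-DE genes about the line
X_SD = 1.5              # sd of interspecies TV1 log2FCs feeding the regression
N_PAIRS = 6786          # size of the default both-significant fixture
FRAC_OUTLIER = 421 / 6786   # fraction of pairs planted outside the 95% PI
OUTLIER_SD = 1.5        # mean extra |log2| residual of disproportionate genes

# --- count simulation ----------------------------------------------------
N_REPS = 4
BASELINE_LOG_MEAN = 7.0     # log2 mean count of an average gene (~128)
BASELINE_LOG_SD = 1.5       # gene-to-gene spread of baseline expression
DISPERSION = 0.05           # NB dispersion alpha
FRAC_EQUIVALENT = 0.55      # genes DE between species in both vertebrae
FRAC_A = 0.10               # genes DE between species in TV6 only
FRAC_B = 0.025              # both-significant genes with a planted PI outlier
SIZE_FACTOR_RANGE = (0.7, 1.3)
FRAC_ONE_TO_ZERO = 0.02
LENGTH_LOG_SD = 0.3         # sd of ln(jerboa length / mouse length)
MEDIAN_LENGTH_BP = 2000.0   # log-normal center of mouse transcript lengths
LENGTH_BASE_SD = 0.8        # spread of mouse transcript lengths (ln scale)
A_EFFECT = (2.0, 0.3)       # |log2FC| law (mean, sd) of TV6-only genes
B_X_EFFECT = (2.0, 0.5)     # |TV1 log2FC| law of B-type (both-DE) genes

# --- tail phantoms -------------------------------------------------------
N_VERTEBRAE = {"mouse": 31, "jerboa": 28}
VOXEL_UM = 9.0
RESIZE = 3
GAP_UM = 270.0              # inter-vertebral unmineralized gap
BONE_INTENSITY = 1.0
BACKGROUND_INTENSITY = 0.0
NEONATE_TV1_UM = {"mouse": 1500.0, "jerboa": 1400.0}
NEONATE_DECAY = 18.0        # e-folding (in vertebra index) of neonate lengths

# --- growth series -------------------------------------------------------
TIMEPOINTS_DAYS = tuple(range(0, 43, 7))        # P0 .. P42, weekly
NASO_ANAL_UM = {"mouse": (30000.0, 85000.0),    # (birth, adult)
                "jerboa": (32000.0, 110000.0)}
ADULT_TAIL_RATIO = {"mouse": 1.0, "jerboa": 1.5}
NEONATE_TAIL_RATIO = 0.5
PEAK_VERTEBRA_CENTER = 6.2  # growth-pulse center (peaks at TV6, plateau 5-8)
PEAK_VERTEBRA_WIDTH = 5.5

# --- growth plates -------------------------------------------------------
ZONE_MEANS_UM = {"total": 450.0, "resting": 90.0,
                 "proliferative": 220.0, "hypertrophic": 140.0}
ZONE_CV = 0.10
CELL_HEIGHT_UM = (18.0, 4.0)    # hypertrophic chondrocyte height (mean, sd)
EDU_P = 0.30
DAILY_RATE_UM = 25.0
CALCEIN_HOURS = 48.0
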