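"""Published summary statistics of the motivating ALS choroid-plexus cohort.

These are the printed group-level summaries (n, mean, SD per variable and
group) of a newly diagnosed ALS cohort (155 patients, of whom 12 carried a
known ALS mutation, and 105 age- and sex-matched healthy controls) in which
lateral-ventricle CP volume was measured with the GMM + SUSAN pipeline this
package implements. They serve two purposes:

* calibration targets for :mod:`plexus.cohort`, so simulated cohorts carry
  the same group structure and correlation structure; and
* inputs to the summary-statistic tests (`anova_from_summary`,
  `ttest_from_summary`, `chisq_contingency`) whose reconstructed test
  statistics are checked against the printed ones.

Only group-level summaries are recorded here; no individual-level data.
"""

from __future__ import annotations

from .stats import GroupSummary

# --- group sizes -----------------------------------------------------------
N_GENETIC_ALS = 12
N_SPORADIC_ALS = 143
N_ALS = N_GENETIC_ALS + N_SPORADIC_ALS  # 155
N_HC = 105

# --- CP volume (mm^3), per subgroup and pooled -----------------------------
CP_VOLUME_SUMMARIES = {
    "genetic_ALS": GroupSummary(n=N_GENETIC_ALS, mean=3161.8, sd=735.1),
    "sporadic_ALS": GroupSummary(n=N_SPORADIC_ALS, mean=2911.3, sd=735.1),
    "HC": GroupSummary(n=N_HC, mean=2454.5, sd=781.3),
}
CP_VOLUME_ALS_POOLED = GroupSummary(n=N_ALS, mean=2930.7, sd=724.8)
CP_VOLUME_HC = GroupSummary(n=N_HC, mean=2454.5, sd=781.3)

# --- demographics and clinical scores --------------------------------------
AGE_SUMMARIES = {
    "genetic_ALS": GroupSummary(n=N_GENETIC_ALS, mean=44.5, sd=10.3),
    "sporadic_ALS": GroupSummary(n=N_SPORADIC_ALS, mean=58.2, sd=8.7),
    "HC": GroupSummary(n=N_HC, mean=57.3, sd=7.9),
}
AGE_ALS_POOLED = GroupSummary(n=N_ALS, mean=57.1, sd=9.6)

# men / women counts per group (genetic ALS, sporadic ALS, HC)
SEX_BY_GROUP = [[9, 3], [85, 58], [55, 50]]
SEX_ALS_POOLED = (94, 61)

EDUCATION_SUMMARIES = {
    "genetic_ALS": GroupSummary(n=N_GENETIC_ALS, mean=8.3, sd=3.3),
    "sporadic_ALS": GroupSummary(n=N_SPORADIC_ALS, mean=9.5, sd=4.0),
    "HC": GroupSummary(n=N_HC, mean=9.9, sd=3.2),
}

ALSFRS_R_SUMMARIES = {
    "genetic_ALS": GroupSummary(n=N_GENETIC_ALS, mean=38.1, sd=6.1),
    "sporadic_ALS": GroupSummary(n=N_SPORADIC_ALS, mean=40.5, sd=3.4),
}
ALSFRS_R_ALS_POOLED = GroupSummary(n=N_ALS, mean=40.3, sd=3.7)

DURATION_SUMMARIES = {  # months from onset to diagnosis
    "genetic_ALS": GroupSummary(n=N_GENETIC_ALS, mean=14.5, sd=9.7),
    "sporadic_ALS": GroupSummary(n=N_SPORADIC_ALS, mean=13.6, sd=6.0),
}
DURATION_ALS_POOLED = GroupSummary(n=N_ALS, mean=13.6, sd=7.9)

BULBAR_ONSET_PROP = {"genetic_ALS": 4 / 12, "sporadic_ALS": 34 / 143,
                     "ALS": 39 / 155}

HARS_SUMMARIES = {
    "genetic_ALS": GroupSummary(n=N_GENETIC_ALS, mean=8.7, sd=5.8),
    "sporadic_ALS": GroupSummary(n=N_SPORADIC_ALS, mean=8.7, sd=5.1),
    "HC": GroupSummary(n=N_HC, mean=4.0, sd=3.9),
}
HDRS_SUMMARIES = {
    "genetic_ALS": GroupSummary(n=N_GENETIC_ALS, mean=10.1, sd=5.9),
    "sporadic_ALS": GroupSummary(n=N_SPORADIC_ALS, mean=10.5, sd=4.9),
    "HC": GroupSummary(n=N_HC, mean=3.4, sd=4.2),
}

# --- blood-CSF barrier -----------------------------------------------------
QALB_ALS = GroupSummary(n=115, mean=5.9, sd=2.8)  # mg/g; 115 of 155 had data
N_QALB = 115

# --- published partial correlations (given age, sex, TIV; ALS patients) ----
PARTIAL_R_ALSFRS = -0.226  # CP volume vs ALSFRS-R
PARTIAL_R_QALB = 0.479     # CP volume vs Qalb

# --- published test statistics for the three-group comparisons -------------
PRINTED_CHI2_SEX = 2.84
PRINTED_T_ALSFRS = 2.16   # genetic vs sporadic ALS, pooled Student t
PRINTED_F_CP_VOLUME = 13.3
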