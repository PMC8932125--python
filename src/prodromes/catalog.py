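"""Built-in symptom catalog: the published childhood/adolescence symptom grid.

76 symptoms across eight clinical dimensions, for a retrospective cohort of
123 future-schizophrenia (SZ) and 82 future-mood-spectrum-disorder (MSD)
patients.  Each row carries the number of symptom-positive patients per
group and, where recorded, the mean (SD) age at onset in years among
positives.

Prevalences are stored as exact count/group-size fractions rather than the
published rounded percentages: the percentages contain at least one internal
inconsistency (bulimia: 10 MSD patients printed as 8.1% although
10/82 = 12.2%), so the counts are treated as authoritative.

``REPORTED_P`` keeps the published per-row p-value column (exact values as
strings, bounds as ``"<x"``).  ``SUSPECT_P_ROWS`` lists the rows whose
published p cannot be recomputed from the published counts under any of the
standard test variants (chi-square with/without continuity correction,
Fisher exact) — internal inconsistencies of the published table, kept for
transparency and excluded from reproduction checks.
"""

from __future__ import annotations

from .cohort import Dimension, SymptomCatalog, SymptomDefinition

__all__ = [
    "builtin_catalog",
    "N_SZ",
    "N_MSD",
    "builtin_counts",
    "REPORTED_P",
    "SUSPECT_P_ROWS",
]

#: Published group sizes.
N_SZ = 123
N_MSD = 82

# (name, dimension, count_sz, mean_sz, sd_sz, count_msd, mean_msd, sd_msd,
#  reported p-value string)
_ROWS: list[tuple] = [
    # -- cognitive and developmental symptoms -------------------------------
    ("Low IQ (<69)", "cognitive_developmental", 24, None, None, 0, None, None, "<0.0001"),
    ("High IQ (>120)", "cognitive_developmental", 1, None, None, 2, None, None, "0.565"),
    ("Heterogeneous or discordant IQ", "cognitive_developmental", 12, None, None, 1, None, None, "0.014"),
    ("Delayed psychomotor development", "cognitive_developmental", 17, None, None, 7, None, None, "0.249"),
    ("Lateralisation disturbances", "cognitive_developmental", 2, None, None, 1, None, None, "1.000"),
    ("Time and space orientation disturbances", "cognitive_developmental", 14, None, None, 5, None, None, "0.071"),
    ("Other psychomotor disturbances", "cognitive_developmental", 12, None, None, 9, None, None, "0.778"),
    ("Speech/language disorders and delay", "cognitive_developmental", 21, None, None, 7, None, None, "0.081"),
    ("Articulation disorders", "cognitive_developmental", 5, None, None, 4, None, None, "1.000"),
    ("Written language disorders", "cognitive_developmental", 13, None, None, 9, None, None, "0.927"),
    ("Mathematics disorders", "cognitive_developmental", 9, None, None, 4, None, None, "0.483"),
    ("Learning disorders not otherwise specified", "cognitive_developmental", 11, None, None, 11, None, None, "0.311"),
    ("Drop in grades and school performance", "cognitive_developmental", 63, 14.3, 2.6, 32, 13.5, 3.0, "0.086"),
    ("Educational underachievement or special educational needs", "cognitive_developmental", 89, 11.5, 4.5, 30, 12.1, 4.0, "<0.001"),
    ("Attention and concentration deficit", "cognitive_developmental", 46, 11.7, 4.6, 26, 13.6, 3.4, "0.403"),
    ("Psycho-affective immaturity", "cognitive_developmental", 25, 12.3, 3.9, 23, 12.4, 4.3, "0.391"),
    ("Tics", "cognitive_developmental", 13, 11.1, 3.7, 3, 11.0, 5.2, "0.071"),
    ("Muteness", "cognitive_developmental", 16, 12.9, 4.1, 4, 9.0, 3.6, "0.055"),
    ("Stuttering", "cognitive_developmental", 3, 11.3, 6.4, 0, None, None, "0.276"),
    # -- functional symptoms ------------------------------------------------
    ("Anorexia", "functional", 35, 13.1, 4.9, 23, 13.0, 4.9, "0.799"),
    ("Binge eating disorder", "functional", 7, 13.4, 2.3, 9, 11.8, 4.6, "0.167"),
    ("Polydipsia", "functional", 3, 16.7, 0.6, 0, None, None, "0.276"),
    ("Bulimia", "functional", 2, 9.5, 9.2, 10, 13.6, 4.3, "0.004"),
    ("Other eating disorders", "functional", 10, 10.0, 6.4, 15, 9.3, 6.3, "0.029"),
    ("Sleep disorders", "functional", 60, 13.3, 4.7, 46, 12.1, 5.1, "0.304"),
    ("Parasomnias", "functional", 27, 14.0, 3.2, 21, 12.9, 5.0, "0.545"),
    ("Enuresis", "functional", 16, 7.3, 3.2, 7, 4.7, 2.7, "0.320"),
    ("Encopresis", "functional", 8, 5.6, 2.9, 0, None, None, "0.023"),
    # -- anxiety-related symptoms -------------------------------------------
    ("Anxiety/separation anxiety", "anxiety", 59, 11.7, 4.9, 52, 11.3, 4.9, "0.030"),
    ("Mental distress/panic attacks", "anxiety", 64, 14.0, 3.1, 38, 12.5, 4.2, "0.425"),
    ("Obsessional elements", "anxiety", 23, 12.5, 4.1, 7, 9.0, 5.0, "0.044"),
    ("Psychosomatic symptoms", "anxiety", 25, 14.0, 3.1, 23, 15.0, 2.0, "0.201"),
    ("Phobic elements", "anxiety", 31, 13.8, 4.1, 4, 14.7, 2.1, "<0.0001"),
    ("Anxiety-related school refusal", "anxiety", 20, 14.1, 3.7, 8, 15.5, 1.7, "0.184"),
    # -- behavioural and impulse-control symptoms ---------------------------
    ("Self-harm behaviours without suicidal intent", "behavioural_impulse", 34, 14.2, 3.3, 26, 15.4, 1.5, "0.531"),
    ("Self-harm behaviours with suicidal intent", "behavioural_impulse", 28, 15.0, 3.2, 24, 14.7, 1.8, "0.235"),
    ("Oppositional behaviours", "behavioural_impulse", 82, 12.1, 4.1, 53, 12.6, 4.5, "0.764"),
    ("Conduct disorders", "behavioural_impulse", 70, 13.6, 3.0, 27, 14.1, 2.8, "0.001"),
    ("Risky behaviour", "behavioural_impulse", 21, 14.4, 2.1, 20, 14.7, 3.0, "0.199"),
    ("Psychomotor agitation without mood component", "behavioural_impulse", 39, 12.5, 4.4, 12, 12.8, 4.5, "0.006"),
    ("Impulsiveness", "behavioural_impulse", 41, 12.6, 4.3, 21, 14.7, 2.8, "0.238"),
    ("Running away from home", "behavioural_impulse", 34, 14.7, 2.9, 13, 15.2, 1.1, "0.049"),
    ("Tobacco use", "behavioural_impulse", 28, 15.6, 1.5, 8, 15.1, 1.5, "0.016"),
    ("Substance abuse", "behavioural_impulse", 40, 15.7, 1.2, 24, 15.2, 1.6, "0.623"),
    ("Absenteeism/dropping out of school", "behavioural_impulse", 57, 14.7, 3.0, 20, 15.0, 3.0, "0.01"),
    # -- mood-related symptoms ----------------------------------------------
    ("Sad mood, depressive affect", "mood", 54, 13.8, 3.0, 58, 13.8, 3.4, "<0.0001"),
    ("Psychomotor retardation", "mood", 28, 15.5, 2.0, 11, 15.2, 2.0, "0.095"),
    ("Morbid ideation", "mood", 33, 14.4, 2.8, 39, 14.1, 2.5, "0.002"),
    ("Self-depreciation", "mood", 39, 13.5, 3.8, 43, 13.3, 3.3, "0.003"),
    ("Anhedonia", "mood", 17, 15.9, 1.1, 21, 15.4, 1.6, "0.033"),
    ("Suicidal ideation", "mood", 46, 15.3, 1.6, 32, 14.8, 2.3, "0.814"),
    ("Mood swings", "mood", 18, 14.3, 3.5, 29, 14.4, 3.2, "0.001"),
    ("Psychomotor agitation with mood component", "mood", 23, 14.0, 3.9, 12, 13.3, 3.1, "0.049"),
    # -- negative symptoms --------------------------------------------------
    # SZ onset prints as the typo "1.,2 (4.4)" in the source table; the true
    # value cannot be recovered, so it is stored as absent.
    ("Withdrawal/social isolation", "negative", 66, None, None, 26, 13.2, 3.9, "0.002"),
    ("Poverty of speech", "negative", 42, 14.7, 2.5, 5, 15.6, 1.3, "<0.0001"),
    ("Emotional coldness", "negative", 34, 15.4, 1.6, 12, 16.0, 1.3, "0.029"),
    ("Relational disturbances involving inhibition", "negative", 39, 10.7, 4.9, 24, 7.9, 4.8, "0.711"),
    ("Reluctance/refusal of contact", "negative", 32, 14.6, 2.7, 13, 15.1, 2.6, "0.085"),
    ("Avolition/aboulia", "negative", 44, 15.5, 1.6, 6, 16.2, 1.0, "<0.0001"),
    ("Self-neglect", "negative", 18, 14.4, 2.1, 3, 12.7, 4.9, "0.011"),
    ("Stereotypies", "negative", 25, 11.5, 5.6, 0, None, None, "<0.0001"),
    # -- positive and discordant symptoms -----------------------------------
    ("Bizarre behaviours", "positive_discordant", 62, 14.7, 2.9, 10, 15.8, 1.2, "<0.0001"),
    ("Disorganisation, dissociation", "positive_discordant", 42, 15.1, 2.2, 6, 16.0, 1.3, "<0.0001"),
    ("Atypical phobias", "positive_discordant", 6, 13.0, 5.3, 0, None, None, "0.083"),
    ("Fragmentation anxiety, fragmentation", "positive_discordant", 14, 13.9, 3.7, 3, 14.7, 0.6, "0.049"),
    ("Thought disorders", "positive_discordant", 43, 15.0, 2.2, 3, 15.7, 1.5, "<0.0001"),
    ("Confabulation/invasive imagery", "positive_discordant", 16, 14.3, 3.0, 2, 15.5, 0.7, "0.009"),
    ("Delusional ideation", "positive_discordant", 39, 15.1, 2.1, 6, 16.0, 1.1, "<0.0001"),
    ("Derealisation/depersonalisation", "positive_discordant", 20, 14.9, 2.1, 5, 16.0, 1.4, "0.029"),
    ("Auditory hallucinations", "positive_discordant", 33, 15.3, 1.4, 7, 15.3, 1.4, "0.001"),
    ("Visual hallucinations", "positive_discordant", 25, 14.6, 2.1, 5, 15.4, 1.5, "0.005"),
    # MSD onset prints a bare mean "15" (single patient): SD stored absent.
    ("Cenesthetic hallucinations", "positive_discordant", 10, 15.3, 2.8, 1, 15.0, None, "0.053"),
    ("Persecution, suspicion", "positive_discordant", 55, 15.3, 1.6, 12, 15.3, 2.7, "<0.0001"),
    ("Other delusions", "positive_discordant", 4, 15.5, 1.3, 2, 16.0, 1.4, "1.000"),
    # -- other --------------------------------------------------------------
    ("Significant modification of behaviour/functioning", "other", 64, 14.9, 1.8, 19, 14.2, 2.2, "<0.0001"),
    ("Diagnosis of attention deficit hyperactivity disorder", "other", 3, 11.0, 3.5, 2, 11.0, 5.7, "1.000"),
]

#: Published p-value column: symptom name -> exact value string or "<bound".
REPORTED_P: dict[str, str] = {row[0]: row[8] for row in _ROWS}

#: Rows whose published p-value is internally inconsistent with the
#: published counts (cannot be recomputed under chi-square with or without
#: continuity correction, nor Fisher's exact test).  Evidence per row:
#: - "Time and space orientation disturbances" (14 vs 5) computes 0.201 but
#:   prints 0.071, the p of the adjacent tics row (13 vs 3).
#: - "Psycho-affective immaturity" (25 vs 23) prints 0.391 while
#:   "Psychosomatic symptoms", with identical counts (25 vs 23), prints the
#:   recomputed value 0.201; one table cannot have two p-values.
#: - "Anorexia" (35 vs 23) computes 0.949, prints 0.799.
#: - "Self-harm behaviours with suicidal intent" (28 vs 24) computes 0.294,
#:   prints 0.235.
#: - "Psychomotor agitation with mood component" (23 vs 12) computes 0.449,
#:   prints 0.049 yet carries no significance star — consistent with a
#:   dropped leading digit.
#: - "Absenteeism/dropping out of school" (57 vs 20) computes 0.0015,
#:   prints "0.01" (truncated display).
SUSPECT_P_ROWS: frozenset[str] = frozenset(
    {
        "Time and space orientation disturbances",
        "Psycho-affective immaturity",
        "Anorexia",
        "Self-harm behaviours with suicidal intent",
        "Psychomotor agitation with mood component",
        "Absenteeism/dropping out of school",
    }
)


def builtin_counts() -> dict[str, tuple[int, int]]:
    """Published symptom-positive counts: name -> (count_sz, count_msd)."""
    return {row[0]: (row[2], row[5]) for row in _ROWS}


def builtin_catalog() -> SymptomCatalog:
    """The full built-in catalog, in table order (the CHAID tie-break order)."""
    return SymptomCatalog(
        [
            SymptomDefinition(
                name=name,
                dimension=Dimension(dimension),
                prev_sz=count_sz / N_SZ,
                prev_msd=count_msd / N_MSD,
                onset_mean_sz=mean_sz,
                onset_sd_sz=sd_sz,
                onset_mean_msd=mean_msd,
                onset_sd_msd=sd_msd,
            )
            for (
                name,
                dimension,
                count_sz,
                mean_sz,
                sd_sz,
                count_msd,
                mean_msd,
                sd_msd,
                _p,
            ) in _ROWS
        ]
    )
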