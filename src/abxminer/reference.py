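"""Published aggregate counts for the French antibiotic-ineffectiveness corpus.

The original analysis corpus (3773 messages by 2335 web users, 46 French
sources, January 2014 – July 2020) is not publicly deposited; only its
aggregate tables are published.  Those aggregates serve two roles here:

* defaults for the synthetic-corpus generator, so generated corpora carry
  the same marginal structure the analysis assumes, and
* inputs to the reporting layer's self-consistency audit, which recomputes
  every published percentage from its count and denominator.
"""

N_POSTS = 3773
N_USERS = 2335

#: users with a determined gender (differs from N_USERS in the source tables)
N_GENDERED_USERS = 2337
N_FEMALE_USERS = 2015

MEAN_POSTS_PER_USER = 1.62  # = 3773 / 2335 rounded to 2 decimals
MEAN_AGE_YEARS = 35.0

#: posts per source (46 sources; the long tail is aggregated as "Other sites")
SOURCE_POSTS = {
    "Twitter (X)": 888, "Doctissimo": 885, "Atoute": 396,
    "Futura-Sciences": 260, "Au feminin": 171, "Meamedica": 125,
    "Les impatientes": 123, "Psychologies": 94, "Onmeda": 94,
    "Journal des femmes": 79, "Maladies rares": 77, "Thyroide": 72,
    "YouTube": 71, "Psychoactif": 68, "Lymphome espoir": 61, "Vinted": 53,
    "Vulgaris Medical": 49, "Ligue contre le cancer": 47, "Andlil": 39,
    "Alarm.asso": 38, "Maman pour la vie": 37, "Pedia Blog": 13,
    "Forum HardWare": 10, "Other sites": 23,
}
SOURCE_USERS = {
    "Twitter (X)": 475, "Doctissimo": 621, "Atoute": 131,
    "Futura-Sciences": 135, "Au feminin": 126, "Meamedica": 124,
    "Les impatientes": 54, "Psychologies": 43, "Onmeda": 85,
    "Journal des femmes": 62, "Maladies rares": 67, "Thyroide": 46,
    "YouTube": 68, "Psychoactif": 42, "Lymphome espoir": 41, "Vinted": 40,
    "Vulgaris Medical": 38, "Ligue contre le cancer": 43, "Andlil": 18,
    "Alarm.asso": 15, "Maman pour la vie": 29, "Pedia Blog": 7,
    "Forum HardWare": 7, "Other sites": 18,
}

#: messages per discussion theme (13 themes found by the biterm topic model);
#: denominator 3770 = assigned messages (3 of the 3773 left unassigned)
N_ASSIGNED_POSTS = 3770
TOPIC_COUNTS = {
    "Ineffective antibiotics": 597,
    "Antibiotics and ear, nose, and throat disorder": 461,
    "Antibiotics and pregnancy": 402,
    "Persistent urinary infections": 356,
    "Mechanisms of resistance": 351,
    "Antibiotics overuse": 301,
    "Inappropriate use of antibiotics": 272,
    "Medical data exchanges": 238,
    "Antibiotics and acne": 226,
    "Gastrointestinal impact of antibiotics": 137,
    "Dental disorders and antibiotics": 109,
    "Sensitivity analysis antibiogram": 77,
    "Nosocomial infection": 66,
}

#: quality-of-life impact mentions per category; a message may carry several
#: categories, so the counts sum to 4792 > 2384 impact-bearing messages
N_IMPACT_POSTS = 2384
IMPACT_RATE = 0.63  # 2384 / 3773
QOL_COUNTS = {
    "physical": 1866, "psychic": 1551, "activity": 745,
    "relational": 602, "financial": 28,
}
N_IMPACT_MENTIONS = 4792  # sum of QOL_COUNTS
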