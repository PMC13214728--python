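"""Published descriptive statistics used as generator calibration targets.

The study reported per-state means and standard deviations (n = 26
participants, within-subject design) for four subjective scales, the three
cognitive-load subscales, and the four per-session eye-tracking aggregates.
These numbers parameterize the default synthetic profiles and are the
reference values for effect-size computations.

State labels: 0 = cognitive overload, 1 = immersion, 2 = distraction.
"""

# scale -> state label -> (mean, sd)
QUESTIONNAIRE_STATS: dict[str, dict[int, tuple[float, float]]] = {
    # NASA-TLX, six 21-point subscales averaged (0-20 anchors assumed)
    "nasa_tlx": {0: (8.974, 5.393), 1: (5.256, 2.290), 2: (6.019, 2.554)},
    # Flow State Scale, 10 items, 1-5 Likert
    "fss": {0: (3.804, 0.541), 1: (4.269, 0.633), 2: (2.992, 1.007)},
    # Distractibility subscale, 13 items, 1-7 Likert
    "distractibility": {0: (2.66, 0.94), 1: (2.25, 0.93), 2: (5.45, 1.16)},
    # Multidimensional cognitive-load scale, 11-point (0-10 anchors assumed)
    "il": {0: (5.76, 2.46), 1: (3.51, 2.30), 2: (4.45, 2.16)},
    "el": {0: (1.82, 1.47), 1: (1.34, 1.67), 2: (2.80, 1.89)},
    "gl": {0: (6.82, 1.96), 1: (7.66, 2.23), 2: (5.17, 2.65)},
}

# metric -> state label -> (mean, sd); durations are cumulative seconds per
# session, counts are event counts per session
METRIC_STATS: dict[str, dict[int, tuple[float, float]]] = {
    "fixation_duration": {0: (14.96, 6.31), 1: (6.73, 3.38), 2: (12.98, 7.73)},
    "fixation_count": {0: (56.46, 21.39), 1: (24.23, 9.98), 2: (41.42, 21.58)},
    "saccade_duration": {0: (3.85, 3.26), 1: (1.02, 0.73), 2: (1.47, 1.09)},
    "saccade_count": {0: (60.42, 47.87), 1: (17.96, 12.89), 2: (23.58, 16.43)},
}

METRIC_NAMES = tuple(METRIC_STATS)
SCALE_NAMES = tuple(QUESTIONNAIRE_STATS)

# questionnaire scale anchors (min, max) used for truncation of simulated
# scores; "21-point" and "11-point" scales are anchored at 0
SCALE_BOUNDS: dict[str, tuple[float, float]] = {
    "nasa_tlx": (0.0, 20.0),
    "fss": (1.0, 5.0),
    "distractibility": (1.0, 7.0),
    "il": (0.0, 10.0),
    "el": (0.0, 10.0),
    "gl": (0.0, 10.0),
}
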