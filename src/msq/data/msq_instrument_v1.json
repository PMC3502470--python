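{
  "version": "msq-1.0",
  "items": [
    {"item_id": 1, "label": "Forward flexion of the arm", "section": "objective", "subscale": "rom", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 2, "label": "Abduction of the arm", "section": "objective", "subscale": "rom", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 3, "label": "Internal rotation of the arm", "section": "objective", "subscale": "rom", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 4, "label": "External rotation of the arm", "section": "objective", "subscale": "rom", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 5, "label": "Range of the hand", "section": "objective", "subscale": "rom", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 6, "label": "Bag lift in 90 degrees abduction and 20 degrees flexion", "section": "objective", "subscale": "strength", "min_points": 0, "max_points": 24, "response_step": 1},
    {"item_id": 7, "label": "Pain at rest", "section": "subjective", "subscale": "pain", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 8, "label": "Pain at night", "section": "subjective", "subscale": "pain", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 9, "label": "Pain during everyday activities", "section": "subjective", "subscale": "pain", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 10, "label": "Pain during overhead activities", "section": "subjective", "subscale": "pain", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 11, "label": "Pain during strenuous activities", "section": "subjective", "subscale": "pain", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 12, "label": "Worst pain intensity", "section": "subjective", "subscale": "pain", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 13, "label": "Open a tight jar", "section": "subjective", "subscale": "work_daily", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 14, "label": "Carry a heavy shopping bag", "section": "subjective", "subscale": "work_daily", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 15, "label": "Wash one's back", "section": "subjective", "subscale": "work_daily", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 16, "label": "Put on a pullover", "section": "subjective", "subscale": "work_daily", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 17, "label": "Comb or wash one's hair", "section": "subjective", "subscale": "work_daily", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 18, "label": "Reach a high shelf", "section": "subjective", "subscale": "work_daily", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 19, "label": "Perform usual work", "section": "subjective", "subscale": "work_daily", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 20, "label": "Perform household chores", "section": "subjective", "subscale": "work_daily", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 21, "label": "Personal hygiene and dressing", "section": "subjective", "subscale": "work_daily", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 22, "label": "Throw a ball overhand", "section": "subjective", "subscale": "sport_recreation", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 23, "label": "Racquet or club sports", "section": "subjective", "subscale": "sport_recreation", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 24, "label": "Swimming", "section": "subjective", "subscale": "sport_recreation", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 25, "label": "Recreational activities requiring arm force", "section": "subjective", "subscale": "sport_recreation", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 26, "label": "Recreational activities with free arm movement", "section": "subjective", "subscale": "sport_recreation", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 27, "label": "Carrying equipment during recreation", "section": "subjective", "subscale": "sport_recreation", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 28, "label": "Social activities with family and friends", "section": "subjective", "subscale": "quality_of_life", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 29, "label": "Feeling capable and confident", "section": "subjective", "subscale": "quality_of_life", "min_points": 0, "max_points": 10, "response_step": 1},
    {"item_id": 30, "label": "Emotional wellbeing despite the shoulder problem", "section": "subjective", "subscale": "quality_of_life", "min_points": 0, "max_points": 10, "response_step": 1}
  ]
}
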