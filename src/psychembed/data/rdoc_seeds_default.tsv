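# Default seed words for the five original RDoC domains.
# These are generic placeholder seeds: replace them with the published
# domain seed-word lists appropriate to your embedding vocabulary.
negative_valence	fear anxiety threat loss sadness guilt shame worry
positive_valence	reward motivation pleasure approach satisfaction gain
cognitive_systems	attention memory perception language planning control
social_processes	social communication attachment empathy affiliation perception
arousal_regulatory	arousal sleep wakefulness circadian alertness regulation
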