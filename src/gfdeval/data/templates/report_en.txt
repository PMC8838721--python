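DIETARY EVALUATION REPORT
=========================
Participant: {participant_id}   Visit: {visit_code}   Cohort: {cohort}

1. NUTRITIONAL STATUS
{nutritional_status}

2. DIET QUALITY
{diet_quality}

3. FLAGGED IMBALANCES AND ADVICE
{advice}
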