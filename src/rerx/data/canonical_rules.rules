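# Canonical 15-rule prediabetes-vs-diabetes reference model.
# Intervals are half-open (low, high]; '=' on a race level is an indicator test.
IF HbA1c <= 5.8 AND FPG <= 122.7 AND LDL <= 101 AND Mexican-American = no THEN prediabetes
IF HbA1c <= 5.8 AND FPG <= 122.7 AND LDL <= 101 AND Mexican-American = yes AND age <= 40 THEN prediabetes
IF HbA1c <= 5.8 AND FPG <= 122.7 AND LDL <= 101 AND Mexican-American = yes AND age > 40 THEN diabetes
IF HbA1c in (5.8, 6.1] AND FPG <= 122.7 AND LDL <= 101 THEN diabetes
IF HbA1c <= 6.1 AND FPG <= 122.7 AND LDL > 101 THEN diabetes
IF HbA1c <= 5.6 AND FPG > 122.7 AND UACR <= 71 THEN prediabetes
IF HbA1c <= 5.6 AND FPG > 122.7 AND UACR > 71 THEN diabetes
IF HbA1c in (5.6, 6.1] AND FPG > 122.7 AND LDL <= 151 THEN diabetes
IF HbA1c in (5.6, 6.1] AND FPG > 122.7 AND LDL > 151 THEN prediabetes
IF HbA1c in (6.1, 6.4] AND LDL <= 142 AND FPG <= 108.5 AND Non-Hispanic Black = no THEN diabetes
IF HbA1c in (6.1, 6.4] AND LDL <= 142 AND FPG <= 108.5 AND Non-Hispanic Black = yes AND UACR <= 6.1 THEN prediabetes
IF HbA1c in (6.1, 6.4] AND LDL <= 142 AND FPG <= 108.5 AND Non-Hispanic Black = yes AND UACR > 6.1 THEN diabetes
IF HbA1c in (6.1, 6.4] AND LDL <= 142 AND FPG > 108.5 THEN diabetes
IF HbA1c in (6.1, 6.4] AND LDL > 142 THEN prediabetes
IF HbA1c > 6.4 THEN diabetes
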