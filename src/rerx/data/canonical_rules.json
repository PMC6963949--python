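{
 "provenance": "canonical 15-rule reference model",
 "rules": [
  {"id": "R1", "conditions": [
    {"attr": "HbA1c", "op": "<=", "value": 5.8},
    {"attr": "FPG", "op": "<=", "value": 122.7},
    {"attr": "LDL", "op": "<=", "value": 101.0},
    {"attr": "Mexican-American", "op": "=", "level": "no"}],
   "then": "prediabetes"},
  {"id": "R2", "conditions": [
    {"attr": "HbA1c", "op": "<=", "value": 5.8},
    {"attr": "FPG", "op": "<=", "value": 122.7},
    {"attr": "LDL", "op": "<=", "value": 101.0},
    {"attr": "Mexican-American", "op": "=", "level": "yes"},
    {"attr": "age", "op": "<=", "value": 40.0}],
   "then": "prediabetes"},
  {"id": "R3", "conditions": [
    {"attr": "HbA1c", "op": "<=", "value": 5.8},
    {"attr": "FPG", "op": "<=", "value": 122.7},
    {"attr": "LDL", "op": "<=", "value": 101.0},
    {"attr": "Mexican-American", "op": "=", "level": "yes"},
    {"attr": "age", "op": ">", "value": 40.0}],
   "then": "diabetes"},
  {"id": "R4", "conditions": [
    {"attr": "HbA1c", "op": "in", "low": 5.8, "high": 6.1},
    {"attr": "FPG", "op": "<=", "value": 122.7},
    {"attr": "LDL", "op": "<=", "value": 101.0}],
   "then": "diabetes"},
  {"id": "R5", "conditions": [
    {"attr": "HbA1c", "op": "<=", "value": 6.1},
    {"attr": "FPG", "op": "<=", "value": 122.7},
    {"attr": "LDL", "op": ">", "value": 101.0}],
   "then": "diabetes"},
  {"id": "R6", "conditions": [
    {"attr": "HbA1c", "op": "<=", "value": 5.6},
    {"attr": "FPG", "op": ">", "value": 122.7},
    {"attr": "UACR", "op": "<=", "value": 71.0}],
   "then": "prediabetes"},
  {"id": "R7", "conditions": [
    {"attr": "HbA1c", "op": "<=", "value": 5.6},
    {"attr": "FPG", "op": ">", "value": 122.7},
    {"attr": "UACR", "op": ">", "value": 71.0}],
   "then": "diabetes"},
  {"id": "R8", "conditions": [
    {"attr": "HbA1c", "op": "in", "low": 5.6, "high": 6.1},
    {"attr": "FPG", "op": ">", "value": 122.7},
    {"attr": "LDL", "op": "<=", "value": 151.0}],
   "then": "diabetes"},
  {"id": "R9", "conditions": [
    {"attr": "HbA1c", "op": "in", "low": 5.6, "high": 6.1},
    {"attr": "FPG", "op": ">", "value": 122.7},
    {"attr": "LDL", "op": ">", "value": 151.0}],
   "then": "prediabetes"},
  {"id": "R10", "conditions": [
    {"attr": "HbA1c", "op": "in", "low": 6.1, "high": 6.4},
    {"attr": "LDL", "op": "<=", "value": 142.0},
    {"attr": "FPG", "op": "<=", "value": 108.5},
    {"attr": "Non-Hispanic Black", "op": "=", "level": "no"}],
   "then": "diabetes"},
  {"id": "R11", "conditions": [
    {"attr": "HbA1c", "op": "in", "low": 6.1, "high": 6.4},
    {"attr": "LDL", "op": "<=", "value": 142.0},
    {"attr": "FPG", "op": "<=", "value": 108.5},
    {"attr": "Non-Hispanic Black", "op": "=", "level": "yes"},
    {"attr": "UACR", "op": "<=", "value": 6.1}],
   "then": "prediabetes"},
  {"id": "R12", "conditions": [
    {"attr": "HbA1c", "op": "in", "low": 6.1, "high": 6.4},
    {"attr": "LDL", "op": "<=", "value": 142.0},
    {"attr": "FPG", "op": "<=", "value": 108.5},
    {"attr": "Non-Hispanic Black", "op": "=", "level": "yes"},
    {"attr": "UACR", "op": ">", "value": 6.1}],
   "then": "diabetes"},
  {"id": "R13", "conditions": [
    {"attr": "HbA1c", "op": "in", "low": 6.1, "high": 6.4},
    {"attr": "LDL", "op": "<=", "value": 142.0},
    {"attr": "FPG", "op": ">", "value": 108.5}],
   "then": "diabetes"},
  {"id": "R14", "conditions": [
    {"attr": "HbA1c", "op": "in", "low": 6.1, "high": 6.4},
    {"attr": "LDL", "op": ">", "value": 142.0}],
   "then": "prediabetes"},
  {"id": "R15", "conditions": [
    {"attr": "HbA1c", "op": ">", "value": 6.4}],
   "then": "diabetes"}
 ]
}
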