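{"patient_id":"EX001","age_years":42,"sex_assigned_at_birth":"female","administrative_sex":"female","problem_list":[],"medical_history":[],"chief_complaints":["chest pain"],"vitals":[{"time":"2023-01-05T12:40:00","kind":"HR","value":92.0},{"time":"2023-01-05T13:20:00","kind":"HR","value":88.0},{"time":"2023-01-05T12:40:00","kind":"RR","value":18.0},{"time":"2023-01-05T12:40:00","kind":"SBP","value":124.0},{"time":"2023-01-05T12:40:00","kind":"TEMP","value":36.8},{"time":"2023-01-05T12:40:00","kind":"SPO2","value":97.0}],"oxygen_records":[{"time":"2023-01-05T13:30:00","device":"room_air","flow_lpm":0.0}],"gcs_records":[["2023-01-05T13:00:00",15]],"home_o2_lpm":0.0,"prior_encounter_count":4,"trigger_time":"2023-01-05T14:00:00"}
{"patient_id":"EX002","age_years":67,"sex_assigned_at_birth":"male","administrative_sex":"male","problem_list":[{"snomed_code":"128462008","status":"active","recorded_time":"2022-06-19T14:00:00"}],"medical_history":[],"chief_complaints":["dyspnea"],"vitals":[{"time":"2023-01-05T12:35:00","kind":"HR","value":104.0},{"time":"2023-01-05T13:25:00","kind":"HR","value":118.0},{"time":"2023-01-05T12:35:00","kind":"RR","value":24.0},{"time":"2023-01-05T12:35:00","kind":"SBP","value":112.0},{"time":"2023-01-05T12:35:00","kind":"TEMP","value":37.1},{"time":"2023-01-05T13:25:00","kind":"SPO2","value":87.0}],"oxygen_records":[{"time":"2023-01-05T13:40:00","device":"nasal_cannula","flow_lpm":4.0}],"gcs_records":[["2023-01-05T13:05:00",15]],"home_o2_lpm":0.0,"prior_encounter_count":12,"trigger_time":"2023-01-05T14:00:00"}
{"patient_id":"EX003","age_years":63,"sex_assigned_at_birth":"female","administrative_sex":"female","problem_list":[],"medical_history":[{"snomed_code":"13645005","status":"history","recorded_time":"2023-01-04T14:00:00"}],"chief_complaints":["cough"],"vitals":[{"time":"2023-01-05T12:50:00","kind":"HR","value":96.0},{"time":"2023-01-05T12:50:00","kind":"RR","value":21.0},{"time":"2023-01-05T12:50:00","kind":"SBP","value":135.0},{"time":"2023-01-05T12:50:00","kind":"TEMP","value":36.4},{"time":"2023-01-05T12:50:00","kind":"SPO2","value":94.0}],"oxygen_records":[{"time":"2023-01-05T13:35:00","device":"room_air","flow_lpm":0.0}],"gcs_records":[["2023-01-05T13:10:00",15]],"home_o2_lpm":0.0,"prior_encounter_count":0,"trigger_time":"2023-01-05T14:00:00"}
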