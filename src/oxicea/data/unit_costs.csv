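item,perspective,category,unit,usd,arm
pulse_oximeter,provider,capital,per_device,149.81,intervention
batteries,provider,recurrent,per_device,1.01,intervention
personnel,provider,recurrent,per_session,0.59,intervention
personnel,provider,recurrent,per_session,0.34,control
training,provider,recurrent,per_session,13.96,intervention
training,provider,recurrent,per_session,7.40,control
oxygen,provider,recurrent,per_m3,0.77,shared
drugs,patient,patient_expense,per_child,1.01,shared
iv_fluids,patient,patient_expense,per_child,0.88,shared
iv_cannula,patient,patient_expense,per_child,0.34,shared
hospital_stay,patient,patient_expense,per_day,1.18,shared
consultation,patient,patient_expense,per_session,0.40,shared
transport,patient,patient_expense,per_km,0.03,shared
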