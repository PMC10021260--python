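name,role,arm,base,min,max,sd,distribution,source
cost_severe_intervention,cost,intervention,25.74,14.87,34.51,3.62,gamma,Trial data
cost_nonsevere_intervention,cost,intervention,3.58,2.84,4.36,0.34,gamma,Trial data
cost_severe_control,cost,control,17.98,14.23,24.55,2.97,gamma,Trial data
cost_nonsevere_control,cost,control,2.14,1.46,2.97,0.33,gamma,Trial data
p_severe_intervention,probability,intervention,0.16,0.05,0.27,0.03,beta,Trial data
p_severe_control,probability,control,0.04,0.01,0.07,0.01,beta,Trial data
sens_intervention,probability,intervention,0.85,0.72,0.98,0.07,beta,Literature
spec_intervention,probability,intervention,0.87,0.73,1.00,0.07,beta,Assumed equal to specificity of IMCI alone
sens_control,probability,control,0.56,0.39,0.73,0.09,beta,Literature
spec_control,probability,control,0.87,0.73,1.00,0.07,beta,Literature
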