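name,description,unit,low,high,default,category
k_r,renal function-curve slope,L/min/mmHg,0.000125,0.000375,0.00025,renal
P_set,renal set-point pressure,mmHg,48,144,96,renal
W_in,water intake rate,L/min,0.0005,0.0015,0.001,thirst
c,cardiac-output volume gain,1/min,2,6,4,cardiac
VB0,unstressed blood volume,L,1.875,5.625,3.75,cardiac
TPR0,basal total peripheral resistance,mmHg min/L,10,30,20,local-circulation
CO_ref,reference cardiac output,L/min,2.5,7.5,5,cardiac
tau,autoregulation time constant,min,200,600,400,autoregulation
NID_d,sodium intake rate,mEq/min,0.07,0.21,0.14,other
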