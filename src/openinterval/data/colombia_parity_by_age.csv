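# Percentage distribution of married women by parity (children ever born)
# within each five-year age group, Colombia surveys 1990-2015, transcribed
# from a published DHS-based compilation. The printed row mean parity is
# carried alongside; 6+ is an open-ended top category.
age_group,year,p0,p1,p2,p3,p4,p5,p6plus,total,mean_printed
15-19,1990,41.6,48.7,7.1,0.9,1.6,0.0,0.0,100,0.72
15-19,1995,33.7,51.5,12.5,1.8,0.0,0.4,0.0,100,0.84
15-19,2000,32.3,53.6,12.9,0.6,0.6,0.0,0.0,100,0.84
15-19,2005,34.8,47.9,15.9,1.3,0.1,0.0,0.0,100,0.84
15-19,2010,36.1,52.0,10.7,1.2,0.0,0.0,0.0,100,0.77
15-19,2015,39.3,49.1,10.5,1.1,0.0,0.0,0.0,100,0.73
20-24,1990,14.6,44.1,29.0,7.5,3.1,1.4,0.2,100,1.46
20-24,1995,16.8,40.5,26.9,11.4,3.5,0.7,0.2,100,1.47
20-24,2000,13.0,44.3,28.7,10.9,2.1,0.8,0.1,100,1.48
20-24,2005,16.6,44.9,26.5,8.4,3.1,0.5,0.1,100,1.38
20-24,2010,17.9,47.5,24.6,7.8,1.8,0.5,0.0,100,1.30
20-24,2015,19.6,48.8,22.4,7.7,1.3,0.2,0.0,100,1.23
25-29,1990,8.7,24.7,30.6,18.0,13.0,3.6,1.4,100,2.19
25-29,1995,8.7,28.8,30.3,19.1,8.7,2.6,1.8,100,2.05
25-29,2000,7.8,26.7,34.9,19.2,7.8,2.3,1.3,100,2.05
25-29,2005,9.1,30.7,31.4,17.4,7.2,2.8,1.4,100,1.97
25-29,2010,11.5,32.2,33.8,14.3,5.8,1.7,0.7,100,1.79
25-29,2015,12.8,34.6,33.3,13.6,3.8,1.4,0.6,100,1.67
30-34,1990,2.2,13.3,28.7,22.6,15.8,10.6,6.9,100,2.97
30-34,1995,5.1,15.5,31.6,22.0,13.3,6.0,6.5,100,2.68
30-34,2000,5.1,17.1,34.4,22.6,12.0,5.3,3.5,100,2.50
30-34,2005,4.5,17.6,33.5,24.4,11.2,4.8,4.0,100,2.51
30-34,2010,5.5,22.0,37.0,19.8,9.2,4.1,2.4,100,2.27
30-34,2015,7.1,23.5,39.5,18.8,6.6,3.0,1.6,100,2.10
35-39,1990,4.4,10.3,22.6,25.1,14.0,7.7,16.1,100,3.25
35-39,1995,2.4,7.8,24.5,25.1,15.8,11.5,12.9,100,3.33
35-39,2000,3.6,11.5,27.8,27.9,14.4,8.0,6.8,100,2.91
35-39,2005,2.4,11.2,32.3,27.1,12.5,6.2,8.2,100,2.89
35-39,2010,3.1,13.9,34.6,25.2,12.0,5.7,5.5,100,2.69
35-39,2015,3.7,17.8,38.1,23.2,9.5,4.0,3.7,100,2.45
40-44,1990,2.5,5.2,16.6,17.9,16.3,11.1,30.5,100,4.02
40-44,1995,2.2,4.6,18.5,25.7,17.8,10.4,20.8,100,3.71
40-44,2000,2.7,6.2,24.6,24.0,17.3,11.3,14.0,100,3.40
40-44,2005,2.3,8.4,27.0,27.9,15.7,8.5,10.2,100,3.15
40-44,2010,2.9,9.4,30.0,28.3,14.0,6.8,8.6,100,2.97
40-44,2015,3.7,11.6,34.4,25.7,10.9,6.7,7.0,100,2.78
45-49,1990,2.8,5.0,7.3,10.9,10.7,13.3,50.0,100,4.72
45-49,1995,2.6,4.7,13.3,20.6,19.1,10.3,29.4,100,4.03
45-49,2000,2.6,5.0,17.4,23.3,16.1,12.7,22.9,100,3.80
45-49,2005,3.1,6.7,21.2,27.3,17.7,9.6,14.4,100,3.39
45-49,2010,2.7,7.6,27.6,27.3,16.2,8.1,10.6,100,3.15
45-49,2015,3.3,10.3,29.7,28.9,13.6,6.1,8.2,100,2.92
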